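"""A small sensitivity/coordinate-accuracy benchmark.

Simulates one implanted event per (size, UPD type, replicate), runs the
caller, and summarises detection and coordinate overlap. A scaled-down
version of the full grid, sized to finish in a few seconds.
"""

from updtrio import benchmark_sensitivity

summary = benchmark_sensitivity(
    sizes=[1_000_000, 5_000_000],
    states=("father_isodisomy", "mother_heterodisomy"),
    replicates=5,
    seed=7,
    flank=2_000_000,
)
print(summary.to_string(index=False))
# sensitivity is the fraction of implants detected with matching
# chromosome, iso/hetero type and parental origin; mean_overlap and
# frac_overlap_90 measure how well the called coordinates recover the
# implanted interval; false_positives counts calls overlapping no implant.
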