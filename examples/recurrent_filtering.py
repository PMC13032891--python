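"""Cross-sample post-processing: recurrent regions and CNV-style filtering.

Regions called as UPD in many unrelated samples usually mark systematic
artifacts (poorly captured regions, segmental duplications) rather than
real events; events whose depth ratio deviates from 1 look like copy
number variants. This script builds a toy multi-sample events table and
applies both filters.
"""

import pandas as pd

from updtrio import (
    filter_events,
    identify_recurrent_regions,
    mark_recurrent_regions,
)
from updtrio.events import EVENT_COLUMNS


def event(sample, chrom, start, end, state, dr=1.0):
    return {
        "sample_id": sample, "chromosome": chrom, "start": start,
        "end": end, "state": state, "n_snps": 200,
        "n_mendelian_errors": 30, "log_likelihood_ratio": 150.0,
        "p_value": 0.0, "depth_ratio_proband": dr,
        "depth_ratio_father": 1.0, "depth_ratio_mother": 1.0,
    }


events = pd.DataFrame(
    [
        # an artifact region called in three unrelated samples
        event("s1", "chr2", 1_000_000, 1_400_000, "father_heterodisomy"),
        event("s2", "chr2", 1_100_000, 1_500_000, "mother_heterodisomy"),
        event("s3", "chr2", 1_050_000, 1_350_000, "father_heterodisomy"),
        # a private, copy-neutral call: the interesting one
        event("s1", "chr8", 5_000_000, 60_000_000, "father_isodisomy"),
        # a private call with a depth ratio of 0.5: likely a deletion
        event("s2", "chr3", 2_000_000, 2_500_000, "mother_isodisomy", dr=0.5),
    ],
    columns=EVENT_COLUMNS,
)

regions = identify_recurrent_regions(events, min_samples=3)
print("recurrent regions:")
print(regions.to_string(index=False))

marked = mark_recurrent_regions(events, regions)
kept = filter_events(marked, depth_bounds=(0.75, 1.25), drop_recurrent=True)
print("\nevents surviving both filters:")
print(kept[["sample_id", "chromosome", "start", "end", "state"]]
      .to_string(index=False))
# Only the private, copy-neutral chr8 isodisomy survives: the chr2 calls
# fall in a region recurrent across 3 samples and the chr3 call's proband
# depth ratio (0.5) points to a heterozygous deletion, not UPD.
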