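# Methods

## The inheritance HMM

`updtrio` models each chromosome of a sequenced trio as a hidden Markov
chain over five inheritance states: normal (biparental Mendelian)
inheritance and the four UPD modes — paternal/maternal isodisomy and
paternal/maternal heterodisomy. Observations are the 27 possible trio
genotype triples at biallelic SNVs, with genotypes collapsed to
alternate-allele counts (phasing is ignored; only allele counts enter
the model).

**Emissions** are conditional on the parental genotypes:
`P(g_P | g_F, g_M, S) = (1 − ε)·P_S + ε/3`. The state-specific
transmission laws `P_S` are exact:

* *Mendelian*: one allele drawn uniformly from each parent, so e.g.
  het × het gives (¼, ½, ¼) over the proband's allele count.
* *Isodisomy* (per parent): one uniformly chosen allele of the
  contributing parent, duplicated — a het parent yields a homozygous
  proband (½ hom-ref, ½ hom-alt), never a het.
* *Heterodisomy* (per parent): both homologs of the contributing parent,
  so the proband copies that parent's genotype.

The non-contributing parent's genotype never enters a UPD emission. The
full observation is the triple, but the parental prior `P(g_F, g_M)` is
state-independent: it multiplies every state's likelihood identically
and cancels in Viterbi comparisons and in the event likelihood ratio,
so it is omitted. This keeps the model free of population allele
frequencies. Each conditional distribution sums to 1 exactly by
construction (mixture of two normalised distributions); a validity check
enforces this to 1e-12 along with row-stochastic transitions.

**ε (default 0.05)** is a uniform genotyping-error mixture over the
three proband genotypes. It bounds every emission away from zero so a
single miscalled genotype (a Mendelian "error" site in normal data, or a
het inside a true isodisomy) shifts the log-likelihood by a finite
amount instead of vetoing a state. It is deliberately larger than raw
genotyping error rates: it also absorbs alignment artifacts and
mosaicism at the cost of slightly flatter evidence per site.

**τ (default 1e-6)** is the per-variant probability of switching to each
other state; the diagonal is 1 − 4τ. The initial distribution gives each
UPD state 1e-6. Transitions are per-variant, not per-base-pair — no
genetic-map or physical-distance scaling, since the observation sequence
is discrete in variant index. τ sets the evidence threshold for opening
an event: a block must accumulate roughly `log(1/τ) ≈ 13.8` nats of
emission advantage to beat the switch penalty, which at typical per-site
evidence (0.3–0.7 nats at informative sites) corresponds to a few tens
of variants. Boundary *placement* within a detected event is governed by
the evidence random walk, not by τ, which is why called coordinates
track implants closely even for 0.5 Mb events. Both ε and τ are exposed
on the API and CLI; the model (all log tables) round-trips through a
plain-text dump for reproducibility.

**Decoding** is Viterbi only — the reported path is the joint maximum a
posteriori state sequence, computed in log space per chromosome, with
ties broken toward the lower state index so normal inheritance is
preferred when likelihoods are equal. No forward–backward marginals and
no Baum–Welch training. A consequence of the genotype-level model worth
knowing: a sufficiently long run of sites where the proband happens to
equal a het parent's genotype is better explained by heterodisomy than
by Mendelian inheritance (per-site advantage log(0.967/0.492) ≈ 0.68
nats at the default ε), so a run of about 21 such consecutive sites can
flip the decoder — astronomically unlikely under independent Mendelian
transmission, and the noiseless-specificity test confirms zero spurious
calls over 20 simulated genomes.

## Events and annotations

Maximal runs of one UPD state become events with coordinates
`[position of first variant, position of last variant]` — first/last
variant of the block, not midpoints between flanking variants
(conservative and reproducible). Per event:

* **Mendelian errors**: sites whose proband genotype has probability
  zero under biparental transmission before smoothing (e.g. hom-ref ×
  hom-ref parents with an alt allele in the child). True UPD events show
  error counts that grow with size; large events with few errors are the
  classic signature of poor capture or consanguinity.
* **Log-likelihood ratio**: Σ over block sites of
  `log e_S − log e_normal`, emission terms only — the transition terms
  are identical under both hypotheses apart from O(log τ) boundary
  terms, and dropping them makes the statistic block-additive.
* **p-value**: Wilks' test, upper tail of χ²(1 df) at 2·LLR, clamped to
  1 when LLR ≤ 0. The reference distribution is a pragmatic standard
  choice (the hypotheses are not strictly nested in the textbook sense
  and sites are not identically distributed); the raw LLR is emitted so
  users can recalibrate. P-values are per-event, uncorrected for the
  number of events — multiple-testing correction is left to the user.
* **Depth ratios**: median DP inside the event over median DP at all
  retained sites outside it, genome-wide, per trio member. Medians
  resist coverage spikes; a zero denominator yields NaN (flagged
  undefined) rather than an exception.

No minimum event size at calling time — every block of ≥1 SNP is
reported, and all thresholds live in the downstream filters, keeping
calling and filtering separable.

## Input handling

Only biallelic SNVs where all three samples have a called diploid
genotype are loaded; indels, multiallelic records and missing genotypes
are dropped, as are X/Y by default (hemizygous genotypes violate the
diploid observation model; `include_sex=True` overrides). Phased and
unphased genotypes are treated identically. Optional QC keeps sites
with GQ > 20 and DP > 30 — strict inequalities, required in all three
samples; missing GQ/DP count as 0 and therefore fail QC when it is
enabled. Coordinates are 1-based inclusive throughout the caller; BED
inputs (exclusion regions, recurrent-region output) convert to/from
0-based half-open at the boundary. Exclusion lists of known-problematic
regions are user-supplied BED3.

## Post-processing

`collapse_events` merges same-chromosome same-type calls of one sample
into a spanning event (counts and LLR summed, p-value recomputed from
the summed LLR, depth ratios recomputed over the merged span when the
trio data is available, NaN otherwise); it is idempotent.
`identify_recurrent_regions` sweeps event endpoints per chromosome and
returns maximal sub-intervals where ≥ `min_samples` *distinct* samples
have an overlapping event — a sample with two overlapping calls counts
once, since cross-sample recurrence (not within-sample fragmentation)
is what flags artifacts. The default threshold max(2, 1% of samples) is
a design choice, exposed as a parameter. `filter_events` implements the
CNV exclusion: drop events where any trio member's depth ratio leaves
[0.75, 1.25] (bounds configurable and not canonical; NaN ratios fail
conservatively), plus optional minimum SNP-count/size and
recurrence-flag filters.

## The simulator and what it does (not) emulate

Each site draws an allele frequency from Beta(0.5, 0.5) (a U-shaped
spectrum), parents from Hardy–Weinberg, and the proband by Mendelian
transmission; implants override the proband (isodisomy: one uniformly
chosen allele of the named parent per site — an unphased approximation
of a single duplicated haplotype; heterodisomy: the parent's genotype
copied). A symmetric genotyping error then replaces each sample's
genotype with a uniformly chosen different one at rate 0.002 (default).
DP is Poisson(60) and GQ is min(Poisson(70), 99) per sample — 60×
WGS-like values under which the GQ>20/DP>30 QC retains most sites.
Variant density defaults to 1/kb uniformly ("genome-like"); an
"exome-like" mode clusters variants into gene-sized blocks covering 2%
of the chromosome. Everything is reproducible from a single seed, and
VCF output is byte-deterministic (fixed placeholder alleles REF=A,
ALT=G).

Deliberately absent from the generator: linkage disequilibrium and
haplotype structure (so consanguinity-like runs of homozygosity cannot
arise and the specificity results do not speak to consanguineous
samples), mosaic/mixed iso-hetero events, coverage waves, variant-
calling artifacts correlated along the genome, and real site-frequency
spectra. Passing benchmarks therefore demonstrate the decoder's
statistical behaviour under the stated generative model, not
performance on real cohorts.

Scoring: a truth event is detected only when an overlapping call
matches its chromosome, iso/hetero type *and* parental origin;
overlapping calls classify it as right (all match), wrong (none) or
uncertain (a mixture); calls overlapping no truth event are false
positives; coordinate accuracy is the fraction of truth bases covered
by the union of matching calls (1-based inclusive base counting
throughout).

## Benchmark problem sizes

The shipped benchmark grid implants one event of
{0.5, 1, 2, 5, 10, 25} Mb per simulated chromosome (implant centred,
5 Mb flanks on each side), 4 UPD types × 20 replicates, at 1 variant/kb
and error 0.002, run fully in memory; the large-event sensitivity check
uses 10 Mb implants. Per-replicate seeds are spawned from one root seed,
so every number is reproducible. These sizes keep a full grid under a
minute on one CPU while straddling the 2 Mb and 5 Mb sensitivity
breakpoints of interest.

## Known limitations

* Trio-only: no duo (single-parent) mode, no genotype calling, no
  multiallelic support, no haploid model for sex chromosomes.
* Depth ratios annotate, they do not call CNVs.
* The χ²(1) p-value is approximate (see above); treat it as a ranking
  statistic.
* Numeric agreement with other UPD callers' internal parameterisations
  is not expected; ε and τ here are explicit, documented choices.
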