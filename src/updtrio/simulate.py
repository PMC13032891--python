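"""Synthetic trio generator with implanted UPD events, plus benchmark scoring.

The generator draws per-site allele frequencies from a Beta law
(default Beta(0.5, 0.5), a U-shaped spectrum with many near-fixed and
many common variants), samples each parent's two alleles independently
(Hardy-Weinberg), and transmits one uniformly chosen allele from each
parent to the proband. Inside an implanted event the proband is
overridden: isodisomy duplicates one uniformly chosen allele of the
named parent per site (an unphased approximation of a single
haplotype), heterodisomy copies the named parent's genotype. A
symmetric genotyping error then replaces each sample's genotype by a
uniformly chosen different genotype at the stated rate. Sites are
independent — there is no linkage disequilibrium, so consanguinity-like
runs of homozygosity do not arise.

Scoring follows the benchmark convention for trio callers: a truth
event counts as detected only when an overlapping call matches its
chromosome, UPD type (iso/hetero) and parental origin; overlapping
calls classify the truth event as right (all match), wrong (none) or
uncertain (a mixture); calls overlapping no truth event are false
positives.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .events import calculate_events
from .hmm import FATHER_HET, FATHER_ISO, MOTHER_HET, MOTHER_ISO, STATES, HmmModel
from .trio_vcf_io import TrioGenotypes

UPD_STATES = STATES[1:]

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1"}


@dataclasses.dataclass
class TruthEvent:
    """An implanted event: 1-based inclusive coordinates and UPD state."""

    chromosome: str
    start: int
    end: int
    state: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("truth event with start > end")
        if self.state not in UPD_STATES:
            raise ValueError(f"unknown UPD state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class SimulationSpec:
    """Parameters of one simulated trio.

    ``density`` is variants per base pair (default 1/kb, genome-like).
    In ``mode="exome"`` variants are restricted to gene-like blocks
    covering ``exome_block_fraction`` of each chromosome, at
    ``exome_density`` within blocks — a qualitative exome/genome
    contrast, not a capture-kit model.
    """

    chromosomes: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"chr1": 40_000_000}
    )
    density: float = 1e-3
    mode: str = "genome"  # "genome" | "exome"
    af_alpha: float = 0.5
    af_beta: float = 0.5
    error_rate: float = 0.002
    dp_mean: float = 60.0
    gq_mean: float = 70.0
    implants: list[TruthEvent] = dataclasses.field(default_factory=list)
    seed: int | None = None
    exome_block_fraction: float = 0.02
    exome_block_size: int = 20_000
    exome_density: float = 1 / 150

    def __post_init__(self) -> None:
        if self.mode not in ("genome", "exome"):
            raise ValueError(f"unknown mode {self.mode!r}")
        by_chrom: dict[str, list[TruthEvent]] = {}
        for ev in self.implants:
            if ev.chromosome not in self.chromosomes:
                raise ValueError(f"implant on unknown {ev.chromosome}")
            if ev.start < 1 or ev.end > self.chromosomes[ev.chromosome]:
                raise ValueError("implant outside chromosome bounds")
            by_chrom.setdefault(ev.chromosome, []).append(ev)
        for evs in by_chrom.values():
            evs = sorted(evs, key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start <= a.end:
                    raise ValueError("implants overlap")


def _positions(
    spec: SimulationSpec, length: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.mode == "genome":
        n = int(round(length * spec.density))
        if n == 0:
            return np.empty(0, dtype=np.int64)
        return np.unique(rng.integers(1, length + 1, size=n))
    # exome-like: variants clustered in blocks
    n_blocks = max(1, int(round(spec.exome_block_fraction * length
                                / spec.exome_block_size)))
    starts = np.sort(
        rng.integers(1, max(2, length - spec.exome_block_size), size=n_blocks)
    )
    pos: list[np.ndarray] = []
    for s in starts:
        k = rng.poisson(spec.exome_block_size * spec.exome_density)
        if k:
            pos.append(rng.integers(s, s + spec.exome_block_size, size=k))
    if not pos:
        return np.empty(0, dtype=np.int64)
    return np.unique(np.concatenate(pos))


def _apply_error(
    g: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Replace each genotype with a uniformly chosen different one at ``rate``."""
    hit = rng.random(g.size) < rate
    shift = 1 + (rng.random(g.size) < 0.5).astype(np.int64)
    out = g.copy()
    out[hit] = (out[hit] + shift[hit]) % 3
    return out


def simulate_trio(
    spec: SimulationSpec, rng: np.random.Generator | None = None
) -> tuple[dict[str, TrioGenotypes], list[TruthEvent]]:
    """Simulate one trio; fully reproducible from ``spec.seed``.

    Returns the per-chromosome trio data and the list of implanted truth
    events (a copy of ``spec.implants``).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    trios: dict[str, TrioGenotypes] = {}
    for chrom, length in spec.chromosomes.items():
        pos = _positions(spec, length, rng)
        n = pos.size
        p = rng.beta(spec.af_alpha, spec.af_beta, size=n)
        gf = rng.binomial(2, p).astype(np.int64)
        gm = rng.binomial(2, p).astype(np.int64)
        allele_f = (rng.random(n) < gf / 2.0).astype(np.int64)
        allele_m = (rng.random(n) < gm / 2.0).astype(np.int64)
        gp = allele_f + allele_m

        for ev in spec.implants:
            if ev.chromosome != chrom:
                continue
            mask = (pos >= ev.start) & (pos <= ev.end)
            parent = gf if ev.state.startswith("father") else gm
            if ev.state.endswith("isodisomy"):
                dup = (rng.random(int(mask.sum())) < parent[mask] / 2.0)
                gp[mask] = 2 * dup.astype(np.int64)
            else:  # heterodisomy: proband copies the parent's genotype
                gp[mask] = parent[mask]

        gf = _apply_error(gf, spec.error_rate, rng)
        gm = _apply_error(gm, spec.error_rate, rng)
        gp = _apply_error(gp, spec.error_rate, rng)

        dp = rng.poisson(spec.dp_mean, size=(3, n)).astype(np.int64)
        gq = np.minimum(rng.poisson(spec.gq_mean, size=(3, n)), 99).astype(
            np.int64
        )
        trios[chrom] = TrioGenotypes(
            chromosome=chrom,
            positions=pos,
            gt_father=gf,
            gt_mother=gm,
            gt_proband=gp,
            dp_father=dp[0],
            dp_mother=dp[1],
            dp_proband=dp[2],
            gq_father=gq[0],
            gq_mother=gq[1],
            gq_proband=gq[2],
        )
    return trios, list(spec.implants)


def write_trio_vcf(
    trios: Mapping[str, TrioGenotypes],
    path: str | Path,
    proband_id: str = "PROBAND",
    father_id: str = "FATHER",
    mother_id: str = "MOTHER",
) -> None:
    """Write a sorted multi-sample VCF (GT:GQ:DP) for the trio.

    Synthetic sites carry fixed placeholder alleles (REF=A, ALT=G) so the
    output is byte-deterministic for a given trio.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=updtrio-simulator\n")
        for chrom, trio in trios.items():
            ln = int(trio.positions[-1]) if len(trio) else 1
            fh.write(f"##contig=<ID={chrom},length={ln}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{father_id}\t{mother_id}\t{proband_id}\n"
        )
        for chrom, trio in trios.items():
            for i in range(len(trio)):
                cells = "\t".join(
                    f"{_GT_STRING[int(getattr(trio, 'gt_' + r)[i])]}:"
                    f"{int(getattr(trio, 'gq_' + r)[i])}:"
                    f"{int(getattr(trio, 'dp_' + r)[i])}"
                    for r in ("father", "mother", "proband")
                )
                fh.write(
                    f"{chrom}\t{int(trio.positions[i])}\t.\tA\tG\t.\tPASS\t.\t"
                    f"GT:GQ:DP\t{cells}\n"
                )


def write_truth(truth: Sequence[TruthEvent], path: str | Path) -> None:
    """Write truth events as TSV (chromosome, start, end, state)."""
    with open(path, "w") as fh:
        fh.write("chromosome\tstart\tend\tstate\n")
        for ev in truth:
            fh.write(f"{ev.chromosome}\t{ev.start}\t{ev.end}\t{ev.state}\n")


def read_truth(path: str | Path) -> list[TruthEvent]:
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    return [
        TruthEvent(r.chromosome, int(r.start), int(r.end), r.state)
        for r in df.itertuples(index=False)
    ]


@dataclasses.dataclass
class TruthScore:
    """Scoring of one truth event against the call set."""

    truth: TruthEvent
    detected: bool
    classification: str | None  # right | wrong | uncertain | None (no overlap)
    overlap_fraction: float | None  # defined only when detected


@dataclasses.dataclass
class EvalResult:
    per_event: list[TruthScore]
    false_positive_count: int


def _overlap(a1: int, b1: int, a2: int, b2: int) -> int:
    """Inclusive-interval overlap in bases."""
    return max(0, min(b1, b2) - max(a1, a2) + 1)


def _union_coverage(truth: TruthEvent, calls: pd.DataFrame) -> float:
    """Fraction of the truth interval covered by the union of the calls."""
    segs = sorted(
        (max(int(s), truth.start), min(int(e), truth.end))
        for s, e in zip(calls["start"], calls["end"])
        if _overlap(int(s), int(e), truth.start, truth.end) > 0
    )
    covered = 0
    cur_start, cur_end = None, None
    for s, e in segs:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / truth.length


def score_run(
    truth: Sequence[TruthEvent], calls: pd.DataFrame
) -> EvalResult:
    """Score a call set against implanted truth events.

    Detection requires an overlapping call with matching chromosome, UPD
    type and parental origin (the full state). Classification over all
    overlapping calls: right = every one matches the state, wrong = none
    does, uncertain = both kinds present. ``overlap_fraction`` is the
    truth bases covered by the union of matching calls over the truth
    length. False positives are calls overlapping no truth event.
    """
    per_event: list[TruthScore] = []
    fp_mask = np.ones(len(calls), dtype=bool)
    for ev in truth:
        same_chrom = calls[calls["chromosome"] == ev.chromosome]
        ov = same_chrom[
            (same_chrom["start"] <= ev.end) & (same_chrom["end"] >= ev.start)
        ]
        fp_mask[ov.index] = False
        if ov.empty:
            per_event.append(TruthScore(ev, False, None, None))
            continue
        matching = ov[ov["state"] == ev.state]
        if len(matching) == len(ov):
            cls = "right"
        elif matching.empty:
            cls = "wrong"
        else:
            cls = "uncertain"
        detected = not matching.empty
        frac = _union_coverage(ev, matching) if detected else None
        per_event.append(TruthScore(ev, detected, cls, frac))
    return EvalResult(per_event, int(fp_mask.sum()))


BENCHMARK_DETAIL_COLUMNS = [
    "size",
    "state",
    "replicate",
    "detected",
    "classification",
    "overlap_fraction",
    "false_positives",
]


def run_benchmark(
    sizes: Sequence[int],
    states: Sequence[str] = UPD_STATES,
    replicates: int = 20,
    seed: int = 0,
    density: float = 1e-3,
    error_rate: float = 0.002,
    flank: int = 5_000_000,
    model: HmmModel | None = None,
    dp_mean: float = 60.0,
    gq_mean: float = 70.0,
) -> pd.DataFrame:
    """Simulate, call and score one implant per (size, state, replicate).

    Each replicate simulates a single chromosome of length
    ``size + 2*flank`` with the implant in the middle, runs the full
    caller (default model unless given) in memory, and scores the result.
    Returns one row per replicate (:data:`BENCHMARK_DETAIL_COLUMNS`).
    """
    jobs = [
        (size, state, rep)
        for size in sizes
        for state in states
        for rep in range(replicates)
    ]
    children = np.random.SeedSequence(seed).spawn(len(jobs))
    rows = []
    for (size, state, rep), child in zip(jobs, children):
        length = int(size) + 2 * flank
        implant = TruthEvent("chr1", flank + 1, flank + int(size), state)
        spec = SimulationSpec(
            chromosomes={"chr1": length},
            density=density,
            error_rate=error_rate,
            dp_mean=dp_mean,
            gq_mean=gq_mean,
            implants=[implant],
        )
        trios, truth = simulate_trio(spec, rng=np.random.default_rng(child))
        calls = calculate_events(trios, model=model, sample_id="sim")
        result = score_run(truth, calls)
        score = result.per_event[0]
        rows.append(
            {
                "size": int(size),
                "state": state,
                "replicate": rep,
                "detected": score.detected,
                "classification": score.classification,
                "overlap_fraction": score.overlap_fraction,
                "false_positives": result.false_positive_count,
            }
        )
    return pd.DataFrame(rows, columns=BENCHMARK_DETAIL_COLUMNS)


def summarize_benchmark(details: pd.DataFrame) -> pd.DataFrame:
    """Aggregate benchmark details per (size, state).

    Columns: sensitivity (fraction detected), mean_overlap and
    frac_overlap_90 over detected events, false_positives (total).
    """
    rows = []
    for (size, state), grp in details.groupby(["size", "state"], sort=True):
        det = grp[grp["detected"]]
        rows.append(
            {
                "size": int(size),
                "state": state,
                "n": len(grp),
                "sensitivity": float(grp["detected"].mean()) if len(grp) else np.nan,
                "mean_overlap": float(det["overlap_fraction"].mean())
                if len(det)
                else np.nan,
                "frac_overlap_90": float(
                    (det["overlap_fraction"] >= 0.9).mean()
                )
                if len(det)
                else np.nan,
                "false_positives": int(grp["false_positives"].sum()),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "size",
            "state",
            "n",
            "sensitivity",
            "mean_overlap",
            "frac_overlap_90",
            "false_positives",
        ],
    )


def benchmark_sensitivity(
    sizes: Sequence[int],
    replicates: int = 20,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Summary table of sensitivity/overlap/false positives per size x state."""
    if replicates == 0:
        return summarize_benchmark(pd.DataFrame(columns=BENCHMARK_DETAIL_COLUMNS))
    details = run_benchmark(sizes, replicates=replicates, seed=seed, **kwargs)
    return summarize_benchmark(details)
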