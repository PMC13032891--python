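"""Load a father-mother-proband trio from a multi-sample VCF.

Only biallelic SNVs where all three samples carry a called diploid
genotype are retained; genotypes are collapsed to alternate-allele counts
(0 hom-ref, 1 het, 2 hom-alt) — phasing is ignored. Sites overlapping a
user-supplied BED of excluded regions are dropped at load time. Sex
chromosomes are excluded by default because hemizygous genotypes violate
the diploid observation model.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping
from pathlib import Path

import numpy as np
from cyvcf2 import VCF
from intervaltree import IntervalTree

from .hmm import encode_triple

SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})

_ROLES = ("father", "mother", "proband")


@dataclasses.dataclass
class TrioGenotypes:
    """Aligned per-variant arrays for one chromosome of a trio.

    Positions are 1-based VCF coordinates, strictly increasing. Genotype
    codes are alternate-allele counts in {0, 1, 2}; missing GQ/DP were
    recorded as 0 at load time.
    """

    chromosome: str
    positions: np.ndarray
    gt_father: np.ndarray
    gt_mother: np.ndarray
    gt_proband: np.ndarray
    dp_father: np.ndarray
    dp_mother: np.ndarray
    dp_proband: np.ndarray
    gq_father: np.ndarray
    gq_mother: np.ndarray
    gq_proband: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        n = self.positions.size
        for field in dataclasses.fields(self):
            if field.name in ("chromosome", "positions"):
                continue
            arr = np.asarray(getattr(self, field.name), dtype=np.int64)
            if arr.size != n:
                raise ValueError(
                    f"{field.name} has length {arr.size}, expected {n}"
                )
            setattr(self, field.name, arr)
        if n and np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"positions not strictly increasing on {self.chromosome}"
            )
        for role in _ROLES:
            gt = getattr(self, f"gt_{role}")
            if gt.size and (gt.min() < 0 or gt.max() > 2):
                raise ValueError(f"gt_{role} contains codes outside {{0,1,2}}")

    def __len__(self) -> int:
        return int(self.positions.size)

    def subset(self, mask: np.ndarray) -> "TrioGenotypes":
        """Return a new TrioGenotypes restricted to ``mask`` (order kept)."""
        kwargs = {"chromosome": self.chromosome}
        for field in dataclasses.fields(self):
            if field.name == "chromosome":
                continue
            kwargs[field.name] = getattr(self, field.name)[mask]
        return TrioGenotypes(**kwargs)


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read BED3 (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            start, end = int(start), int(end)
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def read_trio_vcf(
    path: str | Path,
    proband_id: str,
    father_id: str,
    mother_id: str,
    exclude_regions: str | Path | Mapping[str, IntervalTree] | None = None,
    include_sex: bool = False,
) -> dict[str, TrioGenotypes]:
    """Read a trio from a multi-sample VCF.

    Parameters
    ----------
    path
        VCF 4.x file, plain or bgzipped, with GT and ideally GQ/DP FORMAT
        fields.
    proband_id, father_id, mother_id
        Sample names as they appear in the VCF header.
    exclude_regions
        BED3 path or a mapping of chromosome -> IntervalTree (0-based
        half-open); overlapping sites are dropped.
    include_sex
        Keep X/Y chromosomes (off by default: the model is diploid).

    Returns
    -------
    dict
        chromosome -> :class:`TrioGenotypes` with only biallelic SNVs at
        which all three samples have a called diploid genotype.

    Raises
    ------
    KeyError
        If a named sample is absent from the VCF.
    ValueError
        If the VCF is unsorted (within-chromosome positions decrease or a
        chromosome's records are interleaved with another's).
    """
    if isinstance(exclude_regions, (str, Path)):
        exclude_regions = read_bed(exclude_regions)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (proband_id, father_id, mother_id):
        if name not in samples:
            raise KeyError(
                f"sample {name!r} not found in VCF (has: {', '.join(samples)})"
            )
    cols = {role: samples.index(sid) for role, sid in
            zip(_ROLES, (father_id, mother_id, proband_id))}

    data: dict[str, dict[str, list[int]]] = {}
    finished: set[str] = set()
    current: str | None = None
    last_pos = -1

    for var in vcf:
        chrom = var.CHROM
        if chrom != current:
            if chrom in finished:
                raise ValueError(f"VCF not sorted: {chrom} records interleaved")
            if current is not None:
                finished.add(current)
            current = chrom
            last_pos = -1
        if var.POS < last_pos:
            raise ValueError(
                f"VCF not sorted: {chrom}:{var.POS} after {chrom}:{last_pos}"
            )
        if not include_sex and chrom in SEX_CHROMOSOMES:
            continue
        # biallelic SNV only
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            continue
        if var.ALT[0] not in "ACGT":
            continue
        if var.POS == last_pos:
            continue  # keep the first record at a duplicated position
        if exclude_regions is not None:
            tree = exclude_regions.get(chrom)
            if tree is not None and tree.overlaps(var.POS - 1):
                continue

        genos = var.genotypes
        gts = {}
        ok = True
        for role, idx in cols.items():
            g = genos[idx]
            alleles = g[:-1]  # last entry is the phased flag
            if len(alleles) != 2 or any(a not in (0, 1) for a in alleles):
                ok = False
                break
            gts[role] = alleles[0] + alleles[1]
        if not ok:
            continue

        try:
            gq = var.format("GQ")
        except KeyError:  # field absent from the VCF header
            gq = None
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        site = data.setdefault(
            chrom, {k: [] for k in
                    ["pos"] + [f"{f}_{r}" for f in ("gt", "dp", "gq")
                               for r in _ROLES]}
        )
        site["pos"].append(var.POS)
        last_pos = var.POS
        for role, idx in cols.items():
            site[f"gt_{role}"].append(gts[role])
            site[f"dp_{role}"].append(_format_value(dp, idx))
            site[f"gq_{role}"].append(_format_value(gq, idx))

    return {
        chrom: TrioGenotypes(
            chromosome=chrom,
            positions=np.array(d["pos"], dtype=np.int64),
            **{f"{f}_{r}": np.array(d[f"{f}_{r}"], dtype=np.int64)
               for f in ("gt", "dp", "gq") for r in _ROLES},
        )
        for chrom, d in data.items()
    }


def _format_value(arr, idx: int) -> int:
    """One sample's GQ/DP as a non-negative int; missing becomes 0."""
    if arr is None:
        return 0
    v = np.asarray(arr).reshape(len(arr), -1)[idx, 0]
    if not np.isfinite(float(v)):
        return 0
    return max(int(v), 0)


def apply_qc(
    trio: TrioGenotypes, min_gq: int = 20, min_dp: int = 30
) -> TrioGenotypes:
    """Keep only sites where all six quality values pass strictly.

    A site is retained iff GQ > ``min_gq`` and DP > ``min_dp`` in the
    father, the mother and the proband (strict inequalities). Idempotent;
    never increases the number of sites.
    """
    if min_gq < 0 or min_dp < 0:
        raise ValueError("QC thresholds must be non-negative")
    mask = np.ones(len(trio), dtype=bool)
    for role in _ROLES:
        mask &= getattr(trio, f"gq_{role}") > min_gq
        mask &= getattr(trio, f"dp_{role}") > min_dp
    return trio.subset(mask)


def encode_observations(trio: TrioGenotypes) -> np.ndarray:
    """Encode each site's genotype triple as an integer in [0, 26]."""
    return (
        trio.gt_father * 9 + trio.gt_mother * 3 + trio.gt_proband
    ).astype(np.int64)


# re-export for convenience; the triple codec lives with the model
__all__ = [
    "TrioGenotypes",
    "read_trio_vcf",
    "read_bed",
    "apply_qc",
    "encode_observations",
    "encode_triple",
    "SEX_CHROMOSOMES",
]
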