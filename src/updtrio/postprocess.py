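"""Post-processing of called events: merging, recurrence, CNV filtering.

Fragmented calls of one UPD type on one chromosome can be merged into a
single spanning event; regions called in many unrelated samples point to
systematic artifacts (poorly captured regions, segmental duplications)
and can be flagged; events whose depth ratios deviate from 1 are more
plausibly copy-number variants than copy-neutral UPDs and can be
excluded.
"""

from __future__ import annotations

import math
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .events import EVENT_COLUMNS, depth_ratio, llr_p_value
from .trio_vcf_io import TrioGenotypes

REGION_COLUMNS = ["chromosome", "start", "end", "n_samples"]


def collapse_events(
    events: pd.DataFrame,
    trios: Mapping[str, TrioGenotypes] | None = None,
) -> pd.DataFrame:
    """Merge same-chromosome, same-type events of one sample.

    Each (chromosome, state) group with two or more events becomes a
    single event spanning min(start)..max(end); SNP and Mendelian-error
    counts and the LLR are summed, the p-value is recomputed from the
    summed LLR, and the depth ratios are recomputed over the merged span
    when the trio data is supplied (NaN otherwise). Groups with a single
    event pass through unchanged, so the operation is idempotent.
    """
    if events.empty:
        return events.copy()
    if events["sample_id"].nunique() > 1:
        raise ValueError("collapse_events expects events from a single sample")
    rows = []
    for (chrom, state), grp in events.groupby(
        ["chromosome", "state"], sort=False
    ):
        if len(grp) == 1:
            rows.append(grp.iloc[0].to_dict())
            continue
        start = int(grp["start"].min())
        end = int(grp["end"].max())
        llr = float(grp["log_likelihood_ratio"].sum())
        if trios is not None and chrom in trios:
            pos = trios[chrom].positions
            i0 = int(np.searchsorted(pos, start, side="left"))
            i1 = int(np.searchsorted(pos, end, side="right")) - 1
            dr_p, dr_f, dr_m = depth_ratio(trios, chrom, i0, i1)
        else:
            dr_p = dr_f = dr_m = float("nan")
        rows.append(
            {
                "sample_id": grp["sample_id"].iloc[0],
                "chromosome": chrom,
                "start": start,
                "end": end,
                "state": state,
                "n_snps": int(grp["n_snps"].sum()),
                "n_mendelian_errors": int(grp["n_mendelian_errors"].sum()),
                "log_likelihood_ratio": llr,
                "p_value": llr_p_value(llr),
                "depth_ratio_proband": dr_p,
                "depth_ratio_father": dr_f,
                "depth_ratio_mother": dr_m,
            }
        )
    out = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return out.sort_values(["chromosome", "start"], kind="stable").reset_index(
        drop=True
    )


def identify_recurrent_regions(
    events: pd.DataFrame, min_samples: int | None = None
) -> pd.DataFrame:
    """Maximal regions where >= ``min_samples`` distinct samples have events.

    A sweep over event interval endpoints per chromosome; counting is by
    distinct sample (a sample with two overlapping events counts once).
    ``min_samples`` defaults to ``max(2, ceil(1% of samples))``. Returns a
    table with :data:`REGION_COLUMNS`, coordinates 1-based inclusive.
    """
    if events.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    if min_samples is None:
        min_samples = max(2, math.ceil(0.01 * events["sample_id"].nunique()))
    rows = []
    for chrom, grp in events.groupby("chromosome", sort=False):
        # inclusive [start, end] -> half-open [start, end + 1)
        ivs = [
            (int(s), int(e) + 1, sid)
            for s, e, sid in zip(grp["start"], grp["end"], grp["sample_id"])
        ]
        cuts = sorted({a for a, _, _ in ivs} | {b for _, b, _ in ivs})
        qualifying: list[tuple[int, int]] = []
        for a, b in zip(cuts, cuts[1:]):
            n = len({sid for s, e, sid in ivs if s < b and e > a})
            if n >= min_samples:
                if qualifying and qualifying[-1][1] == a:
                    qualifying[-1] = (qualifying[-1][0], b)
                else:
                    qualifying.append((a, b))
        for a, b in qualifying:
            n = len({sid for s, e, sid in ivs if s < b and e > a})
            rows.append(
                {"chromosome": chrom, "start": a, "end": b - 1, "n_samples": n}
            )
    out = pd.DataFrame(rows, columns=REGION_COLUMNS)
    return out.sort_values(["chromosome", "start"], kind="stable").reset_index(
        drop=True
    )


def mark_recurrent_regions(
    events: pd.DataFrame, regions: pd.DataFrame
) -> pd.DataFrame:
    """Add a boolean ``recurrent`` column: True when an event shares at
    least one base (inclusive coordinates) with any recurrent region."""
    out = events.copy()
    flags = np.zeros(len(out), dtype=bool)
    for i, ev in enumerate(out.itertuples(index=False)):
        sub = regions[regions["chromosome"] == ev.chromosome]
        flags[i] = bool(
            ((sub["start"] <= ev.end) & (sub["end"] >= ev.start)).any()
        )
    out["recurrent"] = flags
    return out


def filter_events(
    events: pd.DataFrame,
    depth_bounds: tuple[float, float] | None = (0.75, 1.25),
    min_snps: int | None = None,
    min_size: int | None = None,
    drop_recurrent: bool = False,
) -> pd.DataFrame:
    """Configurable downstream filters on an events table.

    ``depth_bounds`` drops likely copy-number variants: an event is
    removed when any trio member's depth ratio falls outside the bounds
    (undefined NaN ratios also fail — a copy-neutral call cannot be
    attested). ``min_snps``/``min_size`` drop small blocks;
    ``drop_recurrent`` removes events flagged by
    :func:`mark_recurrent_regions`.
    """
    keep = np.ones(len(events), dtype=bool)
    if depth_bounds is not None:
        lo, hi = depth_bounds
        for col in (
            "depth_ratio_proband",
            "depth_ratio_father",
            "depth_ratio_mother",
        ):
            vals = events[col].to_numpy(dtype=float)
            keep &= np.isfinite(vals) & (vals >= lo) & (vals <= hi)
    if min_snps is not None:
        keep &= events["n_snps"].to_numpy() >= min_snps
    if min_size is not None:
        keep &= (
            events["end"].to_numpy() - events["start"].to_numpy() + 1
        ) >= min_size
    if drop_recurrent:
        if "recurrent" not in events.columns:
            raise ValueError(
                "drop_recurrent requires mark_recurrent_regions first"
            )
        keep &= ~events["recurrent"].to_numpy(dtype=bool)
    return events.loc[keep].reset_index(drop=True)


def write_regions_bed(regions: pd.DataFrame, path) -> None:
    """Write recurrent regions as BED3+1 (0-based half-open, n_samples col 4)."""
    with open(path, "w") as fh:
        for r in regions.itertuples(index=False):
            fh.write(
                f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.n_samples}\n"
            )


def read_regions_bed(path) -> pd.DataFrame:
    """Read BED3+1 recurrent regions back to 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            chrom, start, end, n, *_ = line.split("\t")
            rows.append(
                {
                    "chromosome": chrom,
                    "start": int(start) + 1,
                    "end": int(end),
                    "n_samples": int(n),
                }
            )
    return pd.DataFrame(rows, columns=REGION_COLUMNS)
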