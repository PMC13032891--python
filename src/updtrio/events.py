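"""Turn decoded state paths into annotated UPD events.

Contiguous variants decoded to the same non-normal state become one
event block. Each block is annotated with its Mendelian-error count, a
block-local log-likelihood ratio of the UPD state against normal
inheritance (emission terms only; the transition terms are identical in
both hypotheses up to boundary terms and are omitted), a Wilks p-value
(chi-square, 1 df, on 2*LLR), and the median-depth ratio of each trio
member inside the event versus the rest of the genome — a copy-neutral
event should sit near 1 in all three.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import (
    NORMAL,
    STATES,
    HmmModel,
    build_model,
    mendelian_proband_distribution,
    viterbi,
    path_emission_loglik,
)
from .trio_vcf_io import TrioGenotypes, apply_qc, encode_observations

logger = logging.getLogger(__name__)

EVENT_COLUMNS = [
    "sample_id",
    "chromosome",
    "start",
    "end",
    "state",
    "n_snps",
    "n_mendelian_errors",
    "log_likelihood_ratio",
    "p_value",
    "depth_ratio_proband",
    "depth_ratio_father",
    "depth_ratio_mother",
]

# mendelian_impossible[gf, gm, gp]: True when the proband genotype has
# probability zero under biparental transmission (before error smoothing).
MENDELIAN_IMPOSSIBLE = np.array(
    [
        [
            mendelian_proband_distribution(gf, gm)[gp] == 0.0
            for gp in range(3)
        ]
        for gf in range(3)
        for gm in range(3)
    ]
).reshape(3, 3, 3)


def aggregate_blocks(
    path_states: Sequence[int], positions: np.ndarray
) -> list[tuple[int, int, int]]:
    """Maximal runs of identical non-normal state.

    Returns ``(state, first_index, last_index)`` triples (indices
    inclusive); normal-state runs are not reported. Map to coordinates as
    ``[positions[first], positions[last]]``.
    """
    states = np.asarray(path_states)
    if states.size != np.asarray(positions).size:
        raise ValueError("path and positions are not aligned")
    if states.size == 0:
        return []
    boundaries = np.flatnonzero(np.diff(states) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries - 1, [states.size - 1]])
    return [
        (int(states[i]), int(i), int(j))
        for i, j in zip(starts, ends)
        if states[i] != NORMAL
    ]


def count_mendelian_errors(
    trio: TrioGenotypes, first_index: int, last_index: int
) -> int:
    """Number of trio-incompatible sites in the inclusive index range."""
    sl = slice(first_index, last_index + 1)
    return int(
        MENDELIAN_IMPOSSIBLE[
            trio.gt_father[sl], trio.gt_mother[sl], trio.gt_proband[sl]
        ].sum()
    )


def llr_p_value(llr: float) -> float:
    """Wilks p-value: upper tail of chi-square(1 df) at 2*LLR; 1 if LLR<=0."""
    if llr <= 0:
        return 1.0
    return float(stats.chi2.sf(2.0 * llr, df=1))


def event_llr(
    model: HmmModel,
    observations: Sequence[int],
    state: int,
    first_index: int,
    last_index: int,
) -> tuple[float, float]:
    """Block log-likelihood ratio of ``state`` against normal inheritance.

    Emission terms only, summed over the inclusive index range; the
    p-value is :func:`llr_p_value` of the ratio.
    """
    hi = last_index + 1
    llr = path_emission_loglik(
        model, observations, state, first_index, hi
    ) - path_emission_loglik(model, observations, NORMAL, first_index, hi)
    return llr, llr_p_value(llr)


def depth_ratio(
    trios: Mapping[str, TrioGenotypes],
    chromosome: str,
    first_index: int,
    last_index: int,
) -> tuple[float, float, float]:
    """Median in-event depth over median depth elsewhere, per sample.

    "Elsewhere" is every retained site outside the block genome-wide. A
    zero out-of-event median yields NaN (flagged undefined), never an
    exception. Returned in (proband, father, mother) order.
    """
    sl = slice(first_index, last_index + 1)
    out = []
    for role in ("proband", "father", "mother"):
        inside = getattr(trios[chromosome], f"dp_{role}")[sl]
        rest = []
        for chrom, trio in trios.items():
            dp = getattr(trio, f"dp_{role}")
            if chrom == chromosome:
                rest.append(np.delete(dp, np.s_[sl]))
            else:
                rest.append(dp)
        rest = np.concatenate(rest) if rest else np.empty(0)
        if inside.size == 0 or rest.size == 0:
            out.append(float("nan"))
            continue
        denom = float(np.median(rest))
        out.append(float(np.median(inside)) / denom if denom > 0 else float("nan"))
    return tuple(out)  # type: ignore[return-value]


def calculate_events(
    trios: Mapping[str, TrioGenotypes],
    model: HmmModel | None = None,
    sample_id: str = "proband",
    qc: bool = False,
    min_gq: int = 20,
    min_dp: int = 30,
) -> pd.DataFrame:
    """Full per-chromosome pipeline: decode, aggregate, annotate.

    Each chromosome is encoded and Viterbi-decoded independently;
    non-normal blocks become rows of the returned events table (one row
    per event, :data:`EVENT_COLUMNS`). Deterministic.
    """
    if model is None:
        model = build_model()
    if qc:
        trios = {c: apply_qc(t, min_gq, min_dp) for c, t in trios.items()}

    rows = []
    for chrom, trio in trios.items():
        obs = encode_observations(trio)
        path = viterbi(model, obs)
        blocks = aggregate_blocks(path.states, trio.positions)
        logger.info(
            "%s: %d sites, %d event block(s)", chrom, len(trio), len(blocks)
        )
        for state, i0, i1 in blocks:
            llr, p = event_llr(model, obs, state, i0, i1)
            dr_p, dr_f, dr_m = depth_ratio(trios, chrom, i0, i1)
            rows.append(
                {
                    "sample_id": sample_id,
                    "chromosome": chrom,
                    "start": int(trio.positions[i0]),
                    "end": int(trio.positions[i1]),
                    "state": STATES[state],
                    "n_snps": i1 - i0 + 1,
                    "n_mendelian_errors": count_mendelian_errors(trio, i0, i1),
                    "log_likelihood_ratio": llr,
                    "p_value": p,
                    "depth_ratio_proband": dr_p,
                    "depth_ratio_father": dr_f,
                    "depth_ratio_mother": dr_m,
                }
            )
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events(events: pd.DataFrame, path) -> None:
    """Write the events table as TSV (one row per event)."""
    events.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read an events TSV written by :func:`write_events`."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chromosome": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    return df
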