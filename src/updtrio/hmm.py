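"""Five-state inheritance HMM over trio genotype combinations.

The hidden states are the inheritance modes of the proband's chromosome
pair: normal biparental (Mendelian) inheritance, or one of the four
uniparental-disomy modes — paternal/maternal isodisomy (both copies are
the *same* parental homolog, so the proband is homozygous wherever that
parent is informative) and paternal/maternal heterodisomy (both homologs
of one parent, so the proband mirrors that parent's genotype).

Observations are the 27 ordered trio genotype triples
``(gt_father, gt_mother, gt_proband)`` with each genotype coded as the
alternate-allele count 0/1/2. Emissions are conditional distributions
``P(gt_proband | gt_father, gt_mother, state)``: the state-independent
parental prior ``P(gt_father, gt_mother)`` would multiply every state's
emission identically and cancels both in Viterbi comparisons and in the
event likelihood ratio, so it is omitted and no population allele
frequencies are needed.

Each conditional distribution is smoothed with a uniform genotyping-error
component, ``(1 - eps) * P_model + eps / 3``, which keeps all emissions
finite so that isolated genotyping errors do not force state switches.
Transitions are per-variant (no genetic-map distance scaling): stay with
probability ``1 - 4*tau``, switch to each other state with ``tau``.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Sequence

import numpy as np

#: State labels in decoding order; ``normal`` must be index 0 (ties in the
#: Viterbi maximisation are broken toward the lower index, i.e. toward the
#: conservative no-UPD call).
STATES: tuple[str, ...] = (
    "normal",
    "father_isodisomy",
    "father_heterodisomy",
    "mother_isodisomy",
    "mother_heterodisomy",
)

NORMAL, FATHER_ISO, FATHER_HET, MOTHER_ISO, MOTHER_HET = range(5)
N_STATES = 5
N_OBSERVATIONS = 27

#: father<->mother label swap, used by the symmetry property tests.
PARENT_SWAP = (NORMAL, MOTHER_ISO, MOTHER_HET, FATHER_ISO, FATHER_HET)


def encode_triple(gf: int, gm: int, gp: int) -> int:
    """Encode a genotype triple as ``gf*9 + gm*3 + gp`` in ``[0, 26]``."""
    return gf * 9 + gm * 3 + gp


def decode_triple(code: int) -> tuple[int, int, int]:
    """Inverse of :func:`encode_triple`."""
    return code // 9, (code // 3) % 3, code % 3


def mendelian_proband_distribution(gf: int, gm: int) -> np.ndarray:
    """P(proband alt-allele count | parents), one allele drawn uniformly
    from each parent."""
    pf = gf / 2.0
    pm = gm / 2.0
    return np.array(
        [(1 - pf) * (1 - pm), pf * (1 - pm) + (1 - pf) * pm, pf * pm]
    )


_ISO = {
    0: np.array([1.0, 0.0, 0.0]),
    1: np.array([0.5, 0.0, 0.5]),
    2: np.array([0.0, 0.0, 1.0]),
}
_HET = {
    0: np.array([1.0, 0.0, 0.0]),
    1: np.array([0.0, 1.0, 0.0]),
    2: np.array([0.0, 0.0, 1.0]),
}


def upd_proband_distribution(state: int, gf: int, gm: int) -> np.ndarray:
    """P(proband genotype | parents) under a UPD state.

    Isodisomy duplicates one uniformly chosen allele of the contributing
    parent; heterodisomy transmits both of that parent's alleles, so the
    proband copies the parent's genotype. The non-contributing parent's
    genotype does not enter the distribution.
    """
    if state in (FATHER_ISO, FATHER_HET):
        g = gf
    elif state in (MOTHER_ISO, MOTHER_HET):
        g = gm
    else:
        raise ValueError(f"not a UPD state: {state}")
    table = _ISO if state in (FATHER_ISO, MOTHER_ISO) else _HET
    return table[g].copy()


def _state_distribution(state: int, gf: int, gm: int) -> np.ndarray:
    if state == NORMAL:
        return mendelian_proband_distribution(gf, gm)
    return upd_proband_distribution(state, gf, gm)


@dataclasses.dataclass
class StatePath:
    """Decoded hidden-state sequence aligned to the observations."""

    states: np.ndarray
    log_joint: float

    def __len__(self) -> int:
        return len(self.states)


@dataclasses.dataclass
class HmmModel:
    """The five-state inheritance model in log space.

    ``log_emission[s, code]`` stores ``log P(gp | gf, gm, state=s)`` for
    ``code = gf*9 + gm*3 + gp``; rows therefore normalise over ``gp``
    within each ``(gf, gm)`` slice, not over all 27 codes.
    """

    states: tuple[str, ...]
    log_initial: np.ndarray  # (5,)
    log_transition: np.ndarray  # (5, 5)
    log_emission: np.ndarray  # (5, 27)
    epsilon: float
    tau: float

    def validate(self, atol: float = 1e-12) -> None:
        if self.states != STATES:
            raise ValueError("unexpected state set")
        if not (
            np.all(np.isfinite(self.log_initial))
            and np.all(np.isfinite(self.log_transition))
            and np.all(np.isfinite(self.log_emission))
        ):
            raise ValueError("model contains non-finite log probabilities")
        rows = np.exp(self.log_transition).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=atol, rtol=0):
            raise ValueError("transition rows do not sum to 1")
        em = np.exp(self.log_emission).reshape(N_STATES, 9, 3).sum(axis=2)
        if not np.allclose(em, 1.0, atol=atol, rtol=0):
            raise ValueError("conditional emissions do not sum to 1")

    # -- plain-text round trip for reproducibility -------------------------

    def to_text(self) -> str:
        lines = [
            f"epsilon\t{float(self.epsilon)!r}",
            f"tau\t{float(self.tau)!r}",
            "initial\t" + "\t".join(repr(float(x)) for x in self.log_initial),
        ]
        for i, s in enumerate(self.states):
            lines.append(
                f"transition.{s}\t"
                + "\t".join(repr(float(x)) for x in self.log_transition[i])
            )
        for i, s in enumerate(self.states):
            lines.append(
                f"emission.{s}\t"
                + "\t".join(repr(float(x)) for x in self.log_emission[i])
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "HmmModel":
        fields: dict[str, list[float]] = {}
        for line in text.strip().splitlines():
            key, *vals = line.split("\t")
            fields[key] = [float(v) for v in vals]
        model = cls(
            states=STATES,
            log_initial=np.array(fields["initial"]),
            log_transition=np.array(
                [fields[f"transition.{s}"] for s in STATES]
            ),
            log_emission=np.array([fields[f"emission.{s}"] for s in STATES]),
            epsilon=fields["epsilon"][0],
            tau=fields["tau"][0],
        )
        model.validate(atol=1e-9)
        return model


def build_model(
    epsilon: float = 0.05,
    tau: float = 1e-6,
    initial_upd: float = 1e-6,
) -> HmmModel:
    """Construct the default inheritance HMM.

    Parameters
    ----------
    epsilon
        Genotyping-error smoothing rate in ``(0, 0.5)``; each emission is
        ``(1 - epsilon) * P_model(gp | gf, gm, state) + epsilon / 3``.
    tau
        Per-variant state-switch probability in ``(0, 0.1)``; the diagonal
        of the transition matrix is ``1 - 4*tau``. Smaller ``tau`` raises
        the evidence needed to open or close an event and thereby sets the
        effective minimum detectable event length.
    initial_upd
        Initial probability of each UPD state; normal gets the remainder.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon must be in (0, 0.5), got {epsilon}")
    if not 0.0 < tau < 0.1:
        raise ValueError(f"tau must be in (0, 0.1), got {tau}")
    if not 0.0 < initial_upd < 0.25:
        raise ValueError(f"initial_upd must be in (0, 0.25), got {initial_upd}")

    initial = np.full(N_STATES, initial_upd)
    initial[NORMAL] = 1.0 - 4.0 * initial_upd

    transition = np.full((N_STATES, N_STATES), tau)
    np.fill_diagonal(transition, 1.0 - 4.0 * tau)

    emission = np.empty((N_STATES, N_OBSERVATIONS))
    for s in range(N_STATES):
        for gf in range(3):
            for gm in range(3):
                dist = _state_distribution(s, gf, gm)
                smoothed = (1.0 - epsilon) * dist + epsilon / 3.0
                for gp in range(3):
                    emission[s, encode_triple(gf, gm, gp)] = smoothed[gp]

    model = HmmModel(
        states=STATES,
        log_initial=np.log(initial),
        log_transition=np.log(transition),
        log_emission=np.log(emission),
        epsilon=epsilon,
        tau=tau,
    )
    model.validate()
    return model


def viterbi(model: HmmModel, observations: Sequence[int]) -> StatePath:
    """Most-probable joint state path by log-space dynamic programming.

    Ties are broken toward the lower state index at every maximisation,
    so the normal state is preferred when likelihoods are equal. An empty
    observation sequence yields an empty path with ``log_joint = 0``.
    """
    obs = np.asarray(observations, dtype=np.int64)
    if obs.size == 0:
        return StatePath(np.empty(0, dtype=np.int64), 0.0)
    if obs.min() < 0 or obs.max() >= N_OBSERVATIONS:
        raise ValueError("observation code outside [0, 26]")

    n = obs.size
    trans = model.log_transition
    emit = model.log_emission
    backptr = np.empty((n, N_STATES), dtype=np.int8)
    delta = model.log_initial + emit[:, obs[0]]
    idx = np.arange(N_STATES)
    for t in range(1, n):
        scores = delta[:, None] + trans  # scores[i, j]: i -> j
        best_prev = np.argmax(scores, axis=0)  # first max = lowest index
        backptr[t] = best_prev
        delta = scores[best_prev, idx] + emit[:, obs[t]]

    path = np.empty(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = backptr[t, path[t]]
    return StatePath(path, float(delta[path[-1]]))


def path_emission_loglik(
    model: HmmModel,
    observations: Sequence[int],
    state: int,
    start: int = 0,
    end: int | None = None,
) -> float:
    """Sum of log emissions over ``observations[start:end]`` under one state.

    The range is half-open, so the sum decomposes additively:
    ``loglik(a, c) == loglik(a, b) + loglik(b, c)``. An empty range gives 0.
    """
    obs = np.asarray(observations, dtype=np.int64)[start:end]
    if obs.size == 0:
        return 0.0
    return float(model.log_emission[state, obs].sum())
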