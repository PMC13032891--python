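"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from updtrio.hmm import N_OBSERVATIONS, N_STATES, STATES, HmmModel


def brute_force_viterbi(model: HmmModel, obs) -> tuple[np.ndarray, float]:
    """Exhaustive maximum over all 5^n state paths (oracle, n <= 8).

    Vectorised enumeration, independent of the dynamic-programming
    implementation it checks. Returns the best path (lexicographically
    first among ties, since paths are enumerated in lexicographic order)
    and its joint log probability.
    """
    obs = np.asarray(obs, dtype=np.int64)
    n = obs.size
    if n == 0:
        return np.empty(0, dtype=np.int64), 0.0
    paths = np.indices((N_STATES,) * n).reshape(n, -1).T  # (5^n, n), lexicographic
    lp = model.log_initial[paths[:, 0]] + model.log_emission[paths[:, 0], obs[0]]
    for t in range(1, n):
        lp = (
            lp
            + model.log_transition[paths[:, t - 1], paths[:, t]]
            + model.log_emission[paths[:, t], obs[t]]
        )
    best = int(np.argmax(lp))
    return paths[best].copy(), float(lp[best])


def second_best_margin(model: HmmModel, obs, best_lp: float) -> float:
    """Gap between the optimum and the best strictly-worse path."""
    obs = np.asarray(obs, dtype=np.int64)
    n = obs.size
    paths = np.indices((N_STATES,) * n).reshape(n, -1).T
    lp = model.log_initial[paths[:, 0]] + model.log_emission[paths[:, 0], obs[0]]
    for t in range(1, n):
        lp = (
            lp
            + model.log_transition[paths[:, t - 1], paths[:, t]]
            + model.log_emission[paths[:, t], obs[t]]
        )
    worse = lp[lp < best_lp - 1e-12]
    return float(best_lp - worse.max()) if worse.size else np.inf


def random_model(rng: np.random.Generator) -> HmmModel:
    """A random model satisfying the structural invariants.

    Dirichlet transition rows and initial distribution; Dirichlet
    emission distributions per (state, parental combination) — more
    general than the constructed inheritance model, to exercise the
    decoder beyond its default parameterisation.
    """
    initial = rng.dirichlet(np.ones(N_STATES))
    transition = rng.dirichlet(np.ones(N_STATES), size=N_STATES)
    emission = np.empty((N_STATES, N_OBSERVATIONS))
    for s in range(N_STATES):
        for pc in range(9):
            emission[s, pc * 3 : pc * 3 + 3] = rng.dirichlet(np.ones(3))
    model = HmmModel(
        states=STATES,
        log_initial=np.log(initial),
        log_transition=np.log(transition),
        log_emission=np.log(emission),
        epsilon=0.05,
        tau=1e-6,
    )
    model.validate(atol=1e-9)
    return model


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def write_vcf(path, records, samples=("FA", "MO", "PR")):
    """Write a minimal trio VCF for fixtures.

    ``records`` is a list of (chrom, pos, ref, alt, fa, mo, pr) where the
    per-sample entries are FORMAT strings like '0/1:45:60' (GT:GQ:DP).
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(r[0] for r in records):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="q">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="d">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for chrom, pos, ref, alt, fa, mo, pr in records:
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT:GQ:DP\t"
                f"{fa}\t{mo}\t{pr}\n"
            )
    return path
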