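"""Brute-force oracles and miniature deterministic fixtures.

The oracles here are deliberately independent of the simulation engine:
exact enumeration of mate-sampling probabilities on tiny populations, and
the closed-form founder-generation correlation for symmetric binary
margins. The named fixtures are reduced-size scenarios (small N, short
genome) whose expectations are derived analytically, so the stochastic
machinery can be exercised in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genome import Individual
from .mate_choice import MateChoiceModel
from .sim import SimConfig, run_simulation

__all__ = [
    "enumerate_mate_probabilities",
    "binary_pair_correlation",
    "Fixture",
    "FIXTURE_NAMES",
    "make_fixture",
    "run_fixture",
]

MAX_ENUMERATION_SIZE = 6


def enumerate_mate_probabilities(
    population: Sequence[Individual] | tuple[np.ndarray, np.ndarray],
    model: MateChoiceModel,
    var_t: float | None = None,
) -> np.ndarray:
    """Exact mate-sampling probability table for a tiny population.

    Row i gives the probability of each candidate j being drawn as a mate
    for focal individual i: kernel weights with the diagonal (selfing)
    zeroed, renormalized per row. Refuses populations larger than
    ``MAX_ENUMERATION_SIZE`` — this is a test oracle, not a sampler.
    """
    if isinstance(population, tuple):
        x, s = (np.asarray(a) for a in population)
    else:
        x = np.array([ind.x for ind in population], dtype=float)
        s = np.array([ind.group for ind in population])
    n = x.size
    if n > MAX_ENUMERATION_SIZE:
        raise ValueError(
            f"enumeration oracle limited to populations of <= {MAX_ENUMERATION_SIZE}"
        )
    if n < 2:
        raise ValueError("need at least two individuals")
    if model.needs_variance and var_t is None:
        var_t = float(np.var(x))
    table = np.zeros((n, n))
    for i in range(n):
        w = model.weights(x[i], x, s_focal=str(s[i]), s=s, var_t=var_t)
        w = np.asarray(w, dtype=float).copy()
        w[i] = 0.0
        table[i] = w / w.sum()
    return table


def binary_pair_correlation(p_same: float) -> float:
    """Expected Pearson r for founder pairs with symmetric binary margins.

    When both margins are Bernoulli(1/2) on {0, 1} and mates share a source
    with probability ``p_same``, the correlation is ``2 p_same - 1``; with
    ``p_same = alpha/(alpha+1)`` this gives the founder-generation
    r = (alpha - 1)/(alpha + 1).
    """
    if not 0 <= p_same <= 1:
        raise ValueError("p_same must be in [0, 1]")
    return 2.0 * p_same - 1.0


@dataclass
class Fixture:
    """A named miniature scenario with analytically derived expectations."""

    name: str
    description: str
    config: SimConfig
    check: Callable[[int], dict] = field(repr=False)


def _small_genome() -> dict:
    return {"chrom_lengths": [50_000_000, 50_000_000], "recomb_rate": 1e-8}


def _check_founder_calibration(seed: int) -> dict:
    """Generation-1 admixed fraction equals 1/(1+alpha) for every kernel."""
    n = 1000
    results = {}
    ok = True
    for kind in ("stationary", "increasing", "broad", "social"):
        for alpha in (1.0, 4.0, 10.0):
            cfg = SimConfig(
                n=n, generations=1, kind=kind, alpha=alpha, seed=seed,
                snapshot_generations=(), **_small_genome(),
            )
            res = run_simulation(cfg)
            observed = float(res.summary["admixed_fraction"].iloc[0])
            expected = 1.0 / (1.0 + alpha)
            se = math.sqrt(expected * (1 - expected) / n)
            passed = abs(observed - expected) <= 4 * se
            ok &= passed
            results[f"{kind}_alpha{alpha:g}"] = {
                "observed": observed, "expected": expected, "passed": passed,
            }
    return {"passed": ok, "details": results}


def _check_decay_ordering(seed: int) -> dict:
    """Variance-compensating and social kernels outlast the fixed kernels."""
    t = 10
    rs = {}
    for kind in ("stationary", "increasing", "social"):
        cfg = SimConfig(
            n=600, generations=t, kind=kind, alpha=8.0, seed=seed,
            snapshot_generations=(), **_small_genome(),
        )
        rs[kind] = run_simulation(cfg).r_at(t)
    passed = rs["increasing"] > rs["stationary"] and rs["social"] > rs["stationary"]
    return {"passed": bool(passed), "r": rs}


def _check_migration_smoke(seed: int) -> dict:
    """Migrant counts are exact by construction: rate*N per generation, 50/50."""
    cfg = SimConfig(
        n=200, generations=3, kind="random", migration_rate=0.01, seed=seed,
        snapshot_generations=(), keep_population=True, **_small_genome(),
    )
    res = run_simulation(cfg)
    migrants = [ind for ind in res.final_population if ind.is_migrant]
    n_source1 = sum(1 for ind in migrants if ind.x == 1.0)
    passed = len(migrants) == 2 and n_source1 == 1
    return {
        "passed": bool(passed),
        "n_migrants_final": len(migrants),
        "n_source1": n_source1,
    }


def _check_dating_roundtrip(seed: int) -> dict:
    """t_hat recovery from synthetic exponential tract lengths."""
    from .dating import fit_exponential, infer_admixture_time

    rng = np.random.default_rng(seed)
    t_true, m = 20, 0.5
    lam = (t_true + 1) * m
    lengths = rng.exponential(1.0 / lam, size=100_000)
    lam_hat = fit_exponential(lengths)
    t_hat = infer_admixture_time(lam_hat, m)
    se_t = lam / m / math.sqrt(lengths.size)  # delta-method s.e. of t_hat
    passed = abs(t_hat - t_true) <= 4 * se_t
    return {"passed": bool(passed), "t_hat": t_hat, "t_true": t_true}


_REGISTRY: dict[str, tuple[str, Callable[[int], dict], SimConfig]] = {
    "founder-calibration": (
        "All kernels x alpha in {1,4,10}: generation-1 admixed fraction = 1/(1+alpha)",
        _check_founder_calibration,
        SimConfig(n=1000, generations=1, kind="stationary", alpha=4.0,
                  snapshot_generations=(), **_small_genome()),
    ),
    "decay-ordering": (
        "At alpha=8, t=10: r persists under increasing/social, decays under stationary",
        _check_decay_ordering,
        SimConfig(n=600, generations=10, kind="increasing", alpha=8.0,
                  snapshot_generations=(), **_small_genome()),
    ),
    "migration-smoke": (
        "1% continuous migration: exact migrant counts, 50/50 by source",
        _check_migration_smoke,
        SimConfig(n=200, generations=3, kind="random", migration_rate=0.01,
                  snapshot_generations=(), **_small_genome()),
    ),
    "dating-roundtrip": (
        "Synthetic Exp(lambda) tracts: t_hat recovers the true pulse time",
        _check_dating_roundtrip,
        SimConfig(n=200, generations=1, kind="random",
                  snapshot_generations=(), **_small_genome()),
    ),
}

FIXTURE_NAMES = tuple(_REGISTRY)


def make_fixture(name: str) -> Fixture:
    """Look up a named fixture; raises KeyError for unknown names."""
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    description, check, config = _REGISTRY[name]
    return Fixture(name=name, description=description, config=config, check=check)


def run_fixture(name: str, seed: int = 0) -> dict:
    """Run a fixture's check and return its result dictionary."""
    return make_fixture(name).check(seed)
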