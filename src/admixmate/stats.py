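"""Per-generation statistics on mating structure and ancestry.

All functions accept the mating-record table produced by the simulator
(columns ``x_i, x_j, s_i, s_j, migrant_i, migrant_j``, one row per mating
event) or, where noted, a population (list of individuals or an array of
global ancestry proportions x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Individual

__all__ = [
    "mate_correlation",
    "PermutationTestResult",
    "permutation_test",
    "ancestry_variance",
    "hexbin_density",
    "delta_x_distribution",
    "migrant_mating_fraction",
    "group_ancestry_association",
    "is_bimodal",
]


def _pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, pd.DataFrame):
        return pairs["x_i"].to_numpy(float), pairs["x_j"].to_numpy(float)
    xi, xj = pairs
    return np.asarray(xi, dtype=float), np.asarray(xj, dtype=float)


def _as_x(population) -> np.ndarray:
    if isinstance(population, np.ndarray):
        return population.astype(float)
    if len(population) and isinstance(population[0], Individual):
        return np.array([ind.x for ind in population], dtype=float)
    return np.asarray(population, dtype=float)


def mate_correlation(pairs, symmetrize: bool = False) -> float:
    """Pearson correlation of global ancestry proportion over mating pairs.

    One ordered (parent 1, parent 2) record per mating event. Returns NaN —
    not an exception — when either margin is constant, since the
    correlation is undefined for an ancestry-homogeneous generation. With
    ``symmetrize=True`` every pair is counted in both orders, a cross-check
    for the exchangeability of the two parental roles.
    """
    xi, xj = _pair_arrays(pairs)
    if xi.size < 2:
        raise ValueError("need at least two mating records")
    if symmetrize:
        xi, xj = np.concatenate((xi, xj)), np.concatenate((xj, xi))
    if np.ptp(xi) == 0 or np.ptp(xj) == 0:
        return float("nan")
    return float(np.corrcoef(xi, xj)[0, 1])


@dataclass
class PermutationTestResult:
    r_observed: float
    r_permuted: np.ndarray
    p_value: float
    n_perm: int
    alternative: str


def permutation_test(
    pairs,
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    alternative: str = "greater",
) -> PermutationTestResult:
    """Permutation null for the mate correlation.

    The parent-2 column is permuted uniformly ``n_perm`` times and r is
    recomputed; the one-sided empirical p-value toward positive assortment
    is ``(1 + #{r_perm >= r_obs}) / (n_perm + 1)``, so the smallest
    attainable p with 1,000 permutations is just under 0.001 ("the observed
    r never overlapped the permuted distribution"). ``alternative`` may be
    "greater" (default) or "two-sided".
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    rng = rng or np.random.default_rng()
    xi, xj = _pair_arrays(pairs)
    r_obs = mate_correlation((xi, xj))
    r_perm = np.empty(n_perm)
    for k in range(n_perm):
        r_perm[k] = mate_correlation((xi, rng.permutation(xj)))
    if alternative == "greater":
        exceed = np.sum(r_perm >= r_obs)
    else:
        exceed = np.sum(np.abs(r_perm) >= abs(r_obs))
    p = (1 + exceed) / (n_perm + 1)
    return PermutationTestResult(
        r_observed=r_obs,
        r_permuted=r_perm,
        p_value=float(p),
        n_perm=n_perm,
        alternative=alternative,
    )


def ancestry_variance(population) -> float:
    """Population variance (divide-by-N) of global ancestry proportion."""
    x = _as_x(population)
    if x.size < 2:
        raise ValueError("need at least two individuals")
    return float(np.var(x))


def _hex_assign(xi: np.ndarray, xj: np.ndarray, pitch: float) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-center assignment on a pointy-top hex lattice with horizontal
    center spacing `pitch`, via axial coordinates and cube rounding."""
    size = pitch / math.sqrt(3.0)
    q = (math.sqrt(3.0) / 3.0 * xi - xj / 3.0) / size
    r = (2.0 / 3.0 * xj) / size
    # cube rounding
    cx, cz = q, r
    cy = -cx - cz
    rx, ry, rz = np.round(cx), np.round(cy), np.round(cz)
    dx, dy, dz = np.abs(rx - cx), np.abs(ry - cy), np.abs(rz - cz)
    fix_x = (dx > dy) & (dx > dz)
    fix_z = ~fix_x & (dz > dy)
    rx = np.where(fix_x, -ry - rz, rx)
    rz = np.where(fix_z, -rx - ry, rz)
    return rx.astype(np.int64), rz.astype(np.int64)


def hexbin_density(
    pairs,
    binwidth: float = 0.025,
    grid: str = "hex",
    subsample: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """2-D binned density of mating pairs (x_i, x_j), scaled to max 1.

    Bins (x_i, x_j) on a lattice of pitch ``binwidth`` — hexagonal by
    default, or an exactly testable square grid with ``grid="square"`` —
    and rescales counts so the densest cell equals 1. ``subsample`` draws
    that many records without replacement first (small-cohort views use
    n = 100). Returns a table with cell centers, counts and scaled density.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if grid not in ("hex", "square"):
        raise ValueError("grid must be 'hex' or 'square'")
    xi, xj = _pair_arrays(pairs)
    if subsample is not None and subsample < xi.size:
        rng = rng or np.random.default_rng()
        keep = rng.choice(xi.size, size=subsample, replace=False)
        xi, xj = xi[keep], xj[keep]
    if grid == "square":
        ci = np.floor(xi / binwidth).astype(np.int64)
        cj = np.floor(xj / binwidth).astype(np.int64)
        cx = (ci + 0.5) * binwidth
        cy = (cj + 0.5) * binwidth
    else:
        qi, ri = _hex_assign(xi, xj, binwidth)
        size = binwidth / math.sqrt(3.0)
        cx = size * math.sqrt(3.0) * (qi + ri / 2.0)
        cy = size * 1.5 * ri
    table = (
        pd.DataFrame({"cx": np.round(cx, 9), "cy": np.round(cy, 9)})
        .value_counts()
        .rename("count")
        .reset_index()
        .sort_values(["cx", "cy"], ignore_index=True)
    )
    table["density"] = table["count"] / table["count"].max()
    return table


def delta_x_distribution(
    pairs, quantiles: Sequence[float] = (0.05, 0.25, 0.5, 0.75, 0.95), bins: int = 40
) -> dict:
    """Summaries of the absolute mate difference Delta x = |x_i - x_j|."""
    xi, xj = _pair_arrays(pairs)
    dx = np.abs(xi - xj)
    counts, edges = np.histogram(dx, bins=bins, range=(0.0, 1.0))
    return {
        "values": dx,
        "quantiles": pd.Series(np.quantile(dx, quantiles), index=list(quantiles)),
        "hist": counts,
        "bin_edges": edges,
        "mean": float(dx.mean()),
    }


def migrant_mating_fraction(pairs) -> float:
    """Fraction of mating events in which both parents are new migrants.

    Under random mating with a migrant fraction p this is ~p^2; a sustained
    excess indicates migrants preferentially pairing with each other.
    """
    if isinstance(pairs, pd.DataFrame):
        both = pairs["migrant_i"].to_numpy(bool) & pairs["migrant_j"].to_numpy(bool)
    else:
        mi, mj = pairs
        both = np.asarray(mi, bool) & np.asarray(mj, bool)
    return float(both.mean())


def group_ancestry_association(population) -> float:
    """Difference in mean global ancestry proportion between social groups,
    mean(x | group A) - mean(x | group B).

    Equals 1 at founding (groups coincide with sources) and decays toward 0
    as group labels decouple from genetic ancestry. NaN if a group is
    extinct.
    """
    population = list(population)
    xa = [ind.x for ind in population if ind.group == "A"]
    xb = [ind.x for ind in population if ind.group == "B"]
    if not xa or not xb:
        return float("nan")
    return float(np.mean(xa) - np.mean(xb))


def is_bimodal(x, binwidth: float = 0.05) -> bool:
    """Interior-valley heuristic for a bimodal ancestry distribution.

    Histograms x on [0, 1] and declares bimodality when the tallest bin in
    the central valley [0.4, 0.6] is less than half the height of each
    flanking mode (the tallest bins below 0.4 and above 0.6). A coarse,
    documented stand-in for eyeballing the histogram; not a formal dip test.
    """
    x = _as_x(x)
    edges = np.arange(0.0, 1.0 + binwidth / 2, binwidth)
    counts, _ = np.histogram(x, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    valley = counts[(centers >= 0.4) & (centers <= 0.6)]
    left = counts[centers < 0.4]
    right = counts[centers > 0.6]
    if valley.size == 0 or left.size == 0 or right.size == 0:
        return False
    return bool(valley.max() < 0.5 * left.max() and valley.max() < 0.5 * right.max())
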