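"""Mate-choice kernels and weighted mate sampling.

Five kernels assign a non-negative weight psi to each candidate mate j for a
focal individual i; parent 2 of every mating event is drawn proportional to
psi (selfing excluded). All kernels share a single strength parameter alpha:
at founding, when every individual carries pure source ancestry, an
individual is exactly alpha times more likely to draw a mate from its own
source population than from the other one. Equivalently, the expected
admixed-offspring fraction in the first generation is A = 1/(1 + alpha).

Kernels
-------
random
    Uniform weights; alpha is ignored.
stationary
    psi = exp(-c * |xi - xj|) with c = ln(alpha): a fixed "like-with-like"
    exponential preference on global ancestry proportion.
increasing
    The stationary exponent rescaled each generation by the current
    population variance of x, psi = exp(-(c * var0 / var_t) * |xi - xj|),
    so selectiveness grows as the population homogenizes. At t = 0
    (var_t = var0) it coincides with the stationary kernel.
broad
    Gaussian preference psi ∝ exp(-(xi - xj)^2 / (2 sigma^2)) with
    sigma^2 = 1 / (2 ln alpha), the unique width whose endogamy:exogamy
    weight ratio at founding equals alpha.
social
    Two discrete weights by social-group match: 1 - 1/(alpha + 1) within
    group, 1/(alpha + 1) between groups (within:between ratio alpha).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome import Individual

__all__ = [
    "KINDS",
    "MateChoiceModel",
    "alpha_from_admixed_fraction",
    "stationary_weight",
    "increasing_weight",
    "broad_weight",
    "social_weight",
    "sample_mate",
    "sample_mate_index",
]

KINDS = ("random", "stationary", "increasing", "broad", "social")

_GROUP_CODE = {"A": 0, "B": 1}


def alpha_from_admixed_fraction(A: float) -> float:
    """Endogamy strength alpha implied by a first-generation admixed fraction A.

    ``alpha = 1/A - 1``: A = 0.5 gives alpha = 1 (random mating), A = 1 gives
    alpha = 0 (exclusive exogamy), smaller A gives stronger endogamy.
    """
    if not 0 < A <= 1:
        raise ValueError("A must be in (0, 1]")
    return 1.0 / A - 1.0


def _check_x(*xs) -> None:
    for x in xs:
        arr = np.asarray(x, dtype=float)
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("global ancestry proportion must lie in [0, 1]")


def stationary_weight(xi, xj, alpha: float):
    """Exponential like-with-like weight exp(-ln(alpha) * |xi - xj|)."""
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    _check_x(xi, xj)
    d = np.abs(np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float))
    out = np.exp(-math.log(alpha) * d)
    return out if out.ndim else float(out)


def increasing_weight(xi, xj, alpha: float, var_t: float, var_0: float):
    """Variance-rescaled exponential weight.

    ``psi = exp(-(ln(alpha) * var_0 / var_t) * |xi - xj|)``; equals the
    stationary kernel when ``var_t == var_0`` and degenerates to uniform
    weights when ``var_t == 0`` (an ancestry-homogeneous population carries
    no signal to be selective about).
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    if var_t < 0:
        raise ValueError("var_t must be non-negative")
    if var_0 <= 0:
        raise ValueError("var_0 must be positive")
    _check_x(xi, xj)
    d = np.abs(np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float))
    if var_t == 0:
        out = np.ones_like(d)
    else:
        out = np.exp(-(math.log(alpha) * var_0 / var_t) * d)
    return out if out.ndim else float(out)


def broad_weight(xi, xj, alpha: float):
    """Gaussian preference weight with width calibrated to alpha.

    ``psi = exp(-(xi - xj)^2 / (2 sigma^2))`` with ``sigma^2 = 1/(2 ln alpha)``
    so that psi(0)/psi(1) = alpha exactly. The Gaussian normalizing constant
    is dropped (weights are renormalized at sampling). alpha = 1 yields
    uniform weights (the limiting infinite-width case).
    """
    if alpha < 1:
        raise ValueError("alpha must be >= 1")
    _check_x(xi, xj)
    d = np.asarray(xi, dtype=float) - np.asarray(xj, dtype=float)
    if alpha == 1:
        out = np.ones_like(d)
    else:
        out = np.exp(-(d * d) * math.log(alpha))  # 1/(2 sigma^2) = ln(alpha)
    return out if out.ndim else float(out)


def social_weight(si, sj, alpha: float):
    """Two-valued weight by social-group match.

    ``1 - 1/(alpha+1)`` when si == sj, else ``1/(alpha+1)``; the
    within:between ratio is alpha for every alpha >= 0.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    si_a = np.asarray(si)
    sj_a = np.asarray(sj)
    for arr in (si_a, sj_a):
        if not np.all(np.isin(arr, ("A", "B"))):
            raise ValueError("social group labels must be 'A' or 'B'")
    w_between = 1.0 / (alpha + 1.0)
    out = np.where(si_a == sj_a, 1.0 - w_between, w_between)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class MateChoiceModel:
    """One of the five mating kernels with strength alpha.

    Parameters
    ----------
    kind : {"random", "stationary", "increasing", "broad", "social"}
    alpha : float
        Endogamy:exogamy preference ratio at founding. Must be >= 1 for the
        ancestry-similarity kernels; the social kernel accepts any
        alpha >= 0. Ignored by ``random``.
    var0 : float
        Founder-generation variance of global ancestry proportion,
        sigma_x^2(0); used only by the increasing kernel (0.25 for equal
        source contributions).
    """

    kind: str
    alpha: float = 1.0
    var0: float = 0.25

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown mate-choice kind {self.kind!r}")
        if self.kind in ("stationary", "increasing", "broad") and self.alpha < 1:
            raise ValueError("alpha must be >= 1 for ancestry-similarity kernels")
        if self.kind == "social" and self.alpha < 0:
            raise ValueError("alpha must be >= 0 for the social kernel")
        if self.var0 <= 0:
            raise ValueError("var0 must be positive")

    @property
    def needs_variance(self) -> bool:
        return self.kind == "increasing"

    def weights(
        self,
        x_focal: float,
        x: np.ndarray,
        s_focal: str | None = None,
        s: np.ndarray | None = None,
        var_t: float | None = None,
    ) -> np.ndarray:
        """Kernel weights of one focal individual against candidate arrays."""
        if self.kind == "random":
            return np.ones(np.asarray(x).shape, dtype=float)
        if self.kind == "stationary":
            return np.asarray(stationary_weight(x_focal, x, self.alpha))
        if self.kind == "increasing":
            if var_t is None:
                raise ValueError("increasing kernel requires var_t")
            return np.asarray(
                increasing_weight(x_focal, x, self.alpha, var_t, self.var0)
            )
        if self.kind == "broad":
            return np.asarray(broad_weight(x_focal, x, self.alpha))
        # social
        if s_focal is None or s is None:
            raise ValueError("social kernel requires group labels")
        return np.asarray(social_weight(s_focal, s, self.alpha))

    def _exponents(
        self,
        x_focal: float,
        x: np.ndarray,
        s_focal_code: int,
        s_code: np.ndarray,
        var_t: float,
    ) -> np.ndarray:
        """Log-weights up to an additive constant (sampling-safe form)."""
        if self.kind == "random" or self.alpha == 1:
            return np.zeros(x.shape)
        if self.kind == "stationary":
            return -math.log(self.alpha) * np.abs(x - x_focal)
        if self.kind == "increasing":
            if var_t == 0:
                return np.zeros(x.shape)
            return -(math.log(self.alpha) * self.var0 / var_t) * np.abs(x - x_focal)
        if self.kind == "broad":
            d = x - x_focal
            return -math.log(self.alpha) * d * d
        w_between = 1.0 / (self.alpha + 1.0)
        return np.where(
            s_code == s_focal_code, math.log1p(-w_between), math.log(w_between)
        )


def sample_mate_index(
    focal: int,
    x: np.ndarray,
    s_code: np.ndarray,
    model: MateChoiceModel,
    rng: np.random.Generator,
    var_t: float = 0.0,
) -> int:
    """Draw the index of parent 2 proportional to psi, excluding the focal.

    Fast array path used by the simulation engine: ``s_code`` is the
    group label encoded 0/1. Exponent shifting keeps the draw numerically
    stable even when the increasing kernel becomes extremely selective.
    """
    e = model._exponents(x[focal], x, s_code[focal], s_code, var_t)
    w = np.exp(e - e.max())
    w[focal] = 0.0
    cdf = np.cumsum(w)
    total = cdf[-1]
    j = int(np.searchsorted(cdf, rng.random() * total, side="right"))
    return min(j, x.size - 1)


def sample_mate(
    focal: Individual,
    candidates: Sequence[Individual],
    model: MateChoiceModel,
    rng: np.random.Generator,
    var_t: float | None = None,
) -> Individual:
    """Sample one mate for `focal` from `candidates` proportional to psi.

    The focal individual is excluded (no selfing) and weights are
    renormalized over the remaining candidates.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two individuals to form a pair")
    idx_focal = next(
        (k for k, ind in enumerate(candidates) if ind is focal), None
    )
    if idx_focal is None:
        raise ValueError("focal individual must be among the candidates")
    x = np.array([ind.x for ind in candidates], dtype=float)
    s_code = np.array([_GROUP_CODE[ind.group] for ind in candidates], dtype=np.uint8)
    if model.needs_variance and var_t is None:
        var_t = float(np.var(x))
    j = sample_mate_index(idx_focal, x, s_code, model, rng, var_t or 0.0)
    return candidates[j]
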