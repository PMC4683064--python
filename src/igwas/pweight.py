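"""Optimal P-value weights under a Gaussian prior on effect sizes.

The model: the target study's per-SNP Z scores are Z_i ~ N(μ_i, 1), and
prior knowledge (here, a proxy-phenotype GWAS) supplies μ_i ~ N(η_i, σ²).
Marginally Z_i ~ N(η_i, 1 + σ²). A weight vector w ≥ 0 with mean 1
rescales the per-test one-sided level to q·w_i; the expected number of
rejections is then

    E R(w) = Σ_i Φ̄( (Φ̄⁻¹(q·w_i) − η_i) / √(1+σ²) ).

Maximizing this over the simplex-like constraint set {w ≥ 0, mean(w) = 1}
has a closed-form solution per coordinate given the Lagrange multiplier λ:
with t_i = Φ̄⁻¹(q·w_i) and γ² = 1+σ², stationarity reduces to the
quadratic

    (σ²/2γ²)·t_i² + (η_i/γ²)·t_i − η_i²/(2γ²) = ln(λγ),

whose larger root (the one on the concave branch of the power function,
and the one recovering the point-prior Spjøtvoll solution
t_i = η_i/2 + ln(λ)/η_i as σ→0) gives t_i(λ) and w_i(λ) = Φ̄(t_i(λ))/q.
λ is found by monotone bisection so that mean(w(λ)) = 1. Weights are
capped at 1/q so the per-test level never exceeds 1; capped coordinates
stay at the cap while bisection continues on the rest.

The resulting weights are *not* monotone in η: they peak near
η = √(2·ln(λγ)) and decrease for stronger prior signals, which would be
detected at almost any level anyway (their marginal power gain is small,
so mass is better spent on borderline SNPs). Ties in η always receive
equal weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("igwas")

#: |mean(w) - 1| tolerance for the bisection on the multiplier.
MEAN_TOL = 1e-10
MAX_BISECT = 200


@dataclass(frozen=True)
class PriorSpec:
    """Gaussian prior for the weighting step.

    ``eta``: nonnegative prior means, one per SNP (|Z| scaled to the
    target sample size). ``sigma``: prior standard deviation, reflecting
    how imprecisely the proxy phenotype predicts the target (default
    0.25). ``q``: per-test rejection threshold, conventionally 1/S for S
    SNPs tested genome-wide.
    """

    eta: np.ndarray
    sigma: float = 0.25
    q: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        eta = np.atleast_1d(np.asarray(self.eta, dtype=float))
        object.__setattr__(self, "eta", eta)
        if self.q is None:
            object.__setattr__(self, "q", 1.0 / eta.size)
        if eta.size == 0:
            raise ValueError("eta must be nonempty")
        if not np.all(np.isfinite(eta)):
            raise ValueError("eta must be finite")
        if np.any(eta < 0):
            raise ValueError("eta must be nonnegative (prior means are magnitudes)")
        if self.sigma < 0:
            raise ValueError(f"sigma={self.sigma} must be >= 0")
        if not (0.0 < self.q < 1.0):
            raise ValueError(f"q={self.q} outside (0, 1)")

    @property
    def n(self) -> int:
        return self.eta.size


@dataclass
class WeightResult:
    """Solution of the weight optimization.

    ``objective`` is the expected rejection count at the solution;
    ``lagrange_multiplier`` the dual variable of the mean constraint.
    """

    weights: np.ndarray
    lagrange_multiplier: float
    mean_weight: float
    objective: float
    converged: bool
    iterations: int


def expected_rejections(weights, prior: PriorSpec) -> float:
    """Expected number of rejections Σ_i P(P_i ≤ q·w_i) under the prior.

    Each term is the marginal power of a one-sided level-(q·w_i) test when
    Z_i ~ N(η_i, 1+σ²); the level is capped at 1.
    """
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if w.shape != prior.eta.shape:
        raise ValueError(f"length mismatch: {w.shape} weights, {prior.eta.shape} eta")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    gamma = np.sqrt(1.0 + prior.sigma**2)
    level = np.clip(prior.q * w, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = stats.norm.isf(level)  # +inf at level 0, -inf at level 1
        power = stats.norm.sf((t - prior.eta) / gamma)
    return float(np.sum(power))


def _bayes_w_of_c(c: float, eta: np.ndarray, sigma: float, q: float) -> np.ndarray:
    """Per-coordinate weight at multiplier value c = ln(λγ), capped at 1/q.

    Where the stationarity quadratic has no real root (possible only for
    c < 0), the marginal power exceeds λq at every weight, so the
    coordinate sits at the cap.
    """
    gamma = np.sqrt(1.0 + sigma**2)
    w_max = 1.0 / q
    disc = eta**2 + 2.0 * sigma**2 * c
    w = np.full_like(eta, w_max)
    ok = disc >= 0.0
    t = (-eta[ok] + gamma * np.sqrt(disc[ok])) / sigma**2
    w[ok] = stats.norm.sf(t) / q
    return np.clip(w, 0.0, w_max)


def _bisect_multiplier(w_of_x, x0: float = 0.0) -> tuple[float, np.ndarray, int, bool]:
    """Find x with mean(w_of_x(x)) = 1 by doubling bracket + bisection.

    ``w_of_x`` must be (weakly) decreasing in x in every coordinate.
    """
    lo = hi = x0
    step = 1.0
    iterations = 0
    while np.mean(w_of_x(hi)) > 1.0 and iterations < MAX_BISECT:
        hi += step
        step *= 2.0
        iterations += 1
    step = 1.0
    while np.mean(w_of_x(lo)) < 1.0 and iterations < MAX_BISECT:
        lo -= step
        step *= 2.0
        iterations += 1
    if np.mean(w_of_x(lo)) < 1.0 or np.mean(w_of_x(hi)) > 1.0:
        raise RuntimeError(
            f"failed to bracket the multiplier in [{lo}, {hi}] "
            f"(mean at lo {np.mean(w_of_x(lo)):.3g}, "
            f"at hi {np.mean(w_of_x(hi)):.3g})"
        )
    x = 0.5 * (lo + hi)
    for _ in range(MAX_BISECT):
        iterations += 1
        x = 0.5 * (lo + hi)
        mean = float(np.mean(w_of_x(x)))
        if abs(mean - 1.0) <= MEAN_TOL:
            return x, w_of_x(x), iterations, True
        if mean > 1.0:
            lo = x
        else:
            hi = x
        if hi - lo < 1e-15 * max(1.0, abs(x)):
            break
    return x, w_of_x(x), iterations, False


def bayes_weights(prior: PriorSpec) -> WeightResult:
    """Weights maximizing the expected rejections under the Gaussian prior.

    Solves max_w E R(w) s.t. w ≥ 0, mean(w) = 1 via the per-coordinate
    closed form and bisection on the multiplier. With σ = 0 the problem
    degenerates to the point-prior case and is delegated to
    :func:`spjotvoll_weights`.
    """
    eta, sigma, q = prior.eta, prior.sigma, prior.q
    if sigma == 0.0:
        weights = spjotvoll_weights(eta, q)
        return WeightResult(
            weights=weights,
            lagrange_multiplier=float("nan"),
            mean_weight=float(np.mean(weights)),
            objective=expected_rejections(weights, prior),
            converged=True,
            iterations=0,
        )
    if np.all(eta == eta[0]):
        # symmetry + the mean constraint force exact uniformity
        w = np.ones_like(eta)
        return WeightResult(
            weights=w,
            lagrange_multiplier=float("nan"),
            mean_weight=1.0,
            objective=expected_rejections(w, prior),
            converged=True,
            iterations=0,
        )
    gamma = np.sqrt(1.0 + sigma**2)

    c, w, iterations, converged = _bisect_multiplier(
        lambda c: _bayes_w_of_c(c, eta, sigma, q)
    )
    # exact feasibility: a final renormalization (a no-op up to bisection
    # tolerance) guarantees mean(w) = 1 to machine precision
    mean = float(np.mean(w))
    if mean > 0:
        w = np.clip(w / mean, 0.0, 1.0 / q)
    mean = float(np.mean(w))
    if not converged and abs(mean - 1.0) > 1e-8:
        logger.warning("bayes_weights: |mean(w)-1| = %.3g after bisection", mean - 1.0)
    return WeightResult(
        weights=w,
        lagrange_multiplier=float(np.exp(c) / gamma),
        mean_weight=mean,
        objective=expected_rejections(w, prior),
        converged=abs(mean - 1.0) <= 1e-8,
        iterations=iterations,
    )


def spjotvoll_weights(eta, q: float) -> np.ndarray:
    """Optimal weights for the point prior (σ = 0 limit).

    Maximizes Σ Φ̄(Φ̄⁻¹(q·w_i) − η_i) subject to mean(w) = 1, w ≥ 0.
    Stationarity gives t_i = η_i/2 + ln(λ)/η_i for η_i > 0. Coordinates
    with η_i = 0 have constant marginal power q, so they sit at 0 when
    λ > 1, at the cap when λ < 1, and share the residual mass when the
    multiplier lands exactly at 1. An all-zero η returns uniform weights.
    """
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if np.any(eta < 0):
        raise ValueError("eta must be nonnegative")
    if not (0.0 < q < 1.0):
        raise ValueError(f"q={q} outside (0, 1)")
    n = eta.size
    if n == 1 or np.all(eta == eta[0]):
        return np.ones(n)
    w_max = 1.0 / q
    positive = eta > 0.0
    n_zero = int(np.sum(~positive))

    def w_of_logl(logl: float) -> np.ndarray:
        w = np.empty(n)
        t = eta[positive] / 2.0 + logl / eta[positive]
        w[positive] = np.clip(stats.norm.sf(t) / q, 0.0, w_max)
        if n_zero:
            w[~positive] = w_max if logl < 0.0 else (0.0 if logl > 0.0 else 0.0)
        return w

    logl, w, _, converged = _bisect_multiplier(w_of_logl)
    if not converged and n_zero:
        # multiplier landed on the λ = 1 discontinuity: η = 0 coordinates
        # share whatever mass the positive coordinates leave over
        w_pos = np.clip(stats.norm.sf(eta[positive] / 2.0) / q, 0.0, w_max)
        residual = n - float(np.sum(w_pos))
        if 0.0 <= residual / n_zero <= w_max:
            w = np.empty(n)
            w[positive] = w_pos
            w[~positive] = residual / n_zero
    mean = float(np.mean(w))
    if mean > 0:
        w = np.clip(w / mean, 0.0, w_max)
    return w
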