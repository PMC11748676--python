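"""Forward two-state (random telegraph) model of stochastic gene expression.

The promoter switches between a transcriptionally active "on" state
(repressor unbound) and a silent "off" state (repressor bound).  Binding
occurs at the empirical pseudo-first-order rate ``k_a`` (min^-1, valid at
fixed repressor concentration), unbinding at ``k_d`` (min^-1).  While on,
transcripts are produced at rate ``r``; transcripts decay at rate ``gamma``
in either state.  This module provides the closed-form moments of the
stationary mRNA copy-number distribution, the exact analytic pmf, and an
independent matrix (master-equation null-space) oracle for the same pmf.

Everything depends on the rates only through the dimensionless reductions
r/gamma, k_a/gamma, k_d/gamma.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import mpmath as mp
import numpy as np
from scipy.linalg import null_space
from scipy.special import gammaln, hyp1f1


class InvalidRateError(ValueError):
    """A kinetic rate is outside its admissible range."""


class UndefinedOccupancyError(ValueError):
    """k_a = k_d = 0: the promoter occupancy is indeterminate."""


class NumericalInstabilityError(ArithmeticError):
    """A pmf entry could not be evaluated to finite precision."""


class DegenerateChainError(RuntimeError):
    """Truncated master-equation generator has null-space dimension != 1."""


@dataclass(frozen=True)
class RateParams:
    """Kinetic parameters of the telegraph model, all in min^-1.

    r : basal transcription rate in the on state
    gamma : first-order mRNA degradation rate
    k_a : repressor association rate (on -> off)
    k_d : repressor dissociation rate (off -> on)
    """

    r: float
    gamma: float
    k_a: float
    k_d: float

    def __post_init__(self) -> None:
        # r = 0 is admitted for simulation of pure-decay controls
        if not (self.r >= 0):
            raise InvalidRateError(f"r must be >= 0, got {self.r}")
        if not (self.gamma > 0):
            raise InvalidRateError(f"gamma must be > 0, got {self.gamma}")
        if self.k_a < 0 or self.k_d < 0:
            raise InvalidRateError("k_a and k_d must be >= 0")

    def scaled(self, c: float) -> "RateParams":
        """All four rates multiplied by ``c`` (leaves the pmf invariant)."""
        return RateParams(self.r * c, self.gamma * c, self.k_a * c, self.k_d * c)


@dataclass(frozen=True)
class ReducedParams:
    """Rates non-dimensionalized by the degradation rate."""

    r_t: float
    ka_t: float
    kd_t: float


@dataclass
class MomentSummary:
    """Mean and Fano factor of a copy-number sample or model."""

    mu: float
    fano: float
    n_cells: int


@dataclass
class Pmf:
    """Truncated stationary mRNA copy-number distribution.

    ``probs[m]`` is P(m mRNA) for m = 0..m_max; ``tail_mass_bound`` bounds
    the probability excluded by truncation.
    """

    probs: np.ndarray
    m_max: int
    tail_mass_bound: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 1 or len(self.probs) != self.m_max + 1:
            raise ValueError("probs must have length m_max + 1")

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.m_max + 1)

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))

    def variance(self) -> float:
        mu = self.mean()
        return float(np.dot((self.support - mu) ** 2, self.probs))

    def fano(self) -> float:
        mu = self.mean()
        return self.variance() / mu if mu > 0 else 0.0

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. copy numbers (renormalizes the retained mass)."""
        p = self.probs / self.probs.sum()
        return rng.choice(self.m_max + 1, size=n, p=p)


def nondimensionalize(params: RateParams) -> ReducedParams:
    """Divide r, k_a, k_d by gamma; the pmf depends only on these ratios."""
    g = params.gamma
    return ReducedParams(params.r / g, params.k_a / g, params.k_d / g)


def _require_occupancy(params: RateParams) -> None:
    if params.k_a + params.k_d <= 0:
        raise UndefinedOccupancyError(
            "k_a + k_d = 0: promoter occupancy is undefined"
        )


def mean_expression(params: RateParams) -> float:
    """Stationary mean copy number mu = (r/gamma) * k_d/(k_a + k_d).

    r/gamma is the unrepressed mean; the second factor is the fraction of
    time the repressor is not bound.  For k_a = 0 this reduces to r/gamma.
    """
    _require_occupancy(params)
    if params.k_a == 0:
        return params.r / params.gamma
    return (params.r / params.gamma) * params.k_d / (params.k_a + params.k_d)


def fano_factor(params: RateParams) -> float:
    """Stationary Fano factor F = 1 + [k_a/(k_a+k_d)] * r/(gamma+k_a+k_d).

    Equals 1 (Poisson) when k_a = 0 and exceeds 1 otherwise; slow switching
    at fixed occupancy inflates F (transcriptional bursting).
    """
    _require_occupancy(params)
    if params.k_a == 0:
        return 1.0
    s = params.k_a + params.k_d
    return 1.0 + (params.k_a / s) * params.r / (params.gamma + s)


def promoter_on_fraction(params: RateParams) -> float:
    """Stationary probability that the promoter is unbound, k_d/(k_a+k_d)."""
    _require_occupancy(params)
    if params.k_a == 0:
        return 1.0
    return params.k_d / (params.k_a + params.k_d)


def burst_roots(red: ReducedParams) -> tuple[float, float]:
    """Roots (alpha, beta) of x^2 - (r_t+ka_t+kd_t) x + r_t*kd_t.

    These parameters appear in Gaussian-hypergeometric representations of
    the stationary law; they satisfy alpha+beta = r_t+ka_t+kd_t and
    alpha*beta = r_t*kd_t.  alpha carries the "+sqrt" branch.  A discriminant
    within 1e-12 of negative (rounding) is clipped to zero.
    """
    s = red.r_t + red.ka_t + red.kd_t
    disc = s * s - 4.0 * red.r_t * red.kd_t
    if disc < 0:
        if disc < -1e-12:
            raise NumericalInstabilityError(f"negative discriminant {disc}")
        disc = 0.0
    root = math.sqrt(disc)
    return 0.5 * (s + root), 0.5 * (s - root)


def default_m_max(params: RateParams) -> int:
    """Initial truncation: ceil(r/gamma) + 10*sqrt(r/gamma) + 10.

    Covers the unrepressed Poisson envelope; callers grow it geometrically
    until the tail bound is met.
    """
    rt = params.r / params.gamma
    return int(math.ceil(rt + 10.0 * math.sqrt(rt) + 10.0))


def _poisson_pmf(rt: float, m_max: int) -> np.ndarray:
    if rt == 0:
        out = np.zeros(m_max + 1)
        out[0] = 1.0
        return out
    m = np.arange(m_max + 1)
    logp = -rt + m * math.log(rt) - gammaln(m + 1)
    return np.exp(logp)


def _log_pmf_entry(rt: float, ka_t: float, kd_t: float, m: int) -> float:
    """log P(m) via the confluent-hypergeometric stationary law.

    P(m) = e^{-rt} rt^m/m! * (kd_t)_m/(ka_t+kd_t)_m * 1F1(ka_t; ka_t+kd_t+m; rt)

    (Kummer-transformed so the 1F1 series has all-positive terms.)
    """
    c = ka_t + kd_t
    base = (
        -rt
        + m * math.log(rt)
        - gammaln(m + 1)
        + gammaln(kd_t + m)
        - gammaln(kd_t)
        + gammaln(c)
        - gammaln(c + m)
    )
    h = hyp1f1(ka_t, c + m, rt)
    if not np.isfinite(h) or h <= 0:
        # high-precision fallback for extreme parameters
        h_mp = mp.hyp1f1(ka_t, c + m, rt)
        return base + float(mp.log(h_mp))
    return base + math.log(h)


def _analytic_probs(red: ReducedParams, m_max: int) -> np.ndarray:
    rt, ka_t, kd_t = red.r_t, red.ka_t, red.kd_t
    if ka_t == 0 or rt == 0:
        return _poisson_pmf(rt, m_max)
    if kd_t == 0:
        # absorbing off state: all mass decays to m = 0
        probs = np.zeros(m_max + 1)
        probs[0] = 1.0
        return probs
    out = np.empty(m_max + 1)
    for m in range(m_max + 1):
        lp = _log_pmf_entry(rt, ka_t, kd_t, m)
        if not np.isfinite(lp) and lp != -math.inf:
            raise NumericalInstabilityError(f"pmf entry m={m} is not finite")
        out[m] = math.exp(lp)
    return out


def analytic_pmf(
    params: RateParams,
    m_max: int | None = None,
    tail_tol: float = 1e-8,
    grow: float = 1.5,
    m_cap: int = 20000,
) -> Pmf:
    """Exact stationary pmf of the telegraph model, truncated at ``m_max``.

    With ``m_max=None`` the truncation starts at :func:`default_m_max` and
    grows geometrically (factor ``grow``) until the excluded tail mass —
    computed exactly as 1 - sum(probs), each entry being exact — drops
    below ``tail_tol``.  Evaluation is term-wise in log space with a
    high-precision fallback, so it is stable for large r/gamma.
    """
    red = nondimensionalize(params)
    if params.k_a + params.k_d <= 0:
        raise UndefinedOccupancyError("k_a + k_d = 0")
    if m_max is not None:
        probs = _analytic_probs(red, m_max)
        tail = max(0.0, 1.0 - probs.sum())
        return Pmf(probs, m_max, tail)
    m = default_m_max(params)
    while True:
        probs = _analytic_probs(red, m)
        tail = max(0.0, 1.0 - probs.sum())
        if tail < tail_tol:
            return Pmf(probs, m, tail)
        if m >= m_cap:
            raise NumericalInstabilityError(
                f"tail bound {tail} not met at m_max cap {m_cap}"
            )
        m = min(m_cap, int(math.ceil(m * grow)))


def _generator_matrix(red: ReducedParams, m_max: int) -> np.ndarray:
    """Dense generator of the (promoter state, m) chain in reduced time.

    State index: s*(m_max+1) + m with s=0 on, s=1 off.  Transcription out of
    m = m_max is switched off (reflecting truncation), so columns sum to
    zero and the chain keeps a proper stationary law.
    """
    n = m_max + 1
    A = np.zeros((2 * n, 2 * n))
    for s in (0, 1):
        for m in range(n):
            i = s * n + m
            out = 0.0
            if s == 0:
                if red.ka_t > 0:
                    A[n + m, i] += red.ka_t
                    out += red.ka_t
                if m < m_max:  # reflecting truncation at the boundary
                    A[m + 1, i] += red.r_t
                    out += red.r_t
            else:
                A[m, i] += red.kd_t
                out += red.kd_t
            if m > 0:
                A[i - 1, i] += m
                out += m
            A[i, i] -= out
    return A


def steady_state_pmf_matrix(
    params: RateParams,
    m_max: int | None = None,
    tail_tol: float = 1e-8,
    grow: float = 1.5,
    m_cap: int = 20000,
) -> Pmf:
    """Stationary pmf by the master-equation matrix (null-space) method.

    The generator over states (promoter on/off, m <= m_max) is truncated,
    its one-dimensional null space computed by SVD, and the result
    marginalized over promoter state.  Independent of :func:`analytic_pmf`;
    the two agree to ~1e-10 and cross-validate each other.
    """
    red = nondimensionalize(params)
    if params.k_a + params.k_d <= 0:
        raise UndefinedOccupancyError("k_a + k_d = 0")
    if red.kd_t == 0 and red.ka_t > 0:
        m = m_max if m_max is not None else 0
        probs = np.zeros(m + 1)
        probs[0] = 1.0
        return Pmf(probs, m, 0.0)

    def solve(m: int) -> np.ndarray:
        A = _generator_matrix(red, m)
        ns = null_space(A, rcond=None)
        if ns.shape[1] != 1:
            raise DegenerateChainError(
                f"null space dimension {ns.shape[1]} at m_max={m}"
            )
        v = ns[:, 0]
        if v.sum() < 0:
            v = -v
        v = np.clip(v, 0.0, None)
        v /= v.sum()
        return v[: m + 1] + v[m + 1 :]

    if m_max is not None:
        probs = solve(m_max)
        tail = float(10.0 * probs[-1])  # geometric-tail heuristic
        return Pmf(probs, m_max, tail)
    m = default_m_max(params)
    while True:
        probs = solve(m)
        tail = float(10.0 * probs[-1])
        if tail < tail_tol:
            return Pmf(probs, m, tail)
        if m >= m_cap:
            raise NumericalInstabilityError(f"tail bound not met at cap {m_cap}")
        m = min(m_cap, int(math.ceil(m * grow)))


def moments_from_counts(counts: np.ndarray) -> MomentSummary:
    """Sample mean and Fano factor (unbiased variance) of per-cell counts."""
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    if n < 2:
        raise ValueError("need at least 2 cells for moment estimation")
    mu = float(counts.mean())
    var = float(counts.var(ddof=1))
    fano = var / mu if mu > 0 else 0.0
    return MomentSummary(mu=mu, fano=fano, n_cells=n)
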