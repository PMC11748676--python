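"""Moment-based inversion of the telegraph model.

Given a per-cell mRNA copy-number table, the auxiliary rates r (basal
transcription, from a repressor-deletion strain via mu = r/gamma) and gamma
(degradation, from a post-rifampicin decay fit), the stationary mean and
corrected Fano factor are inverted for the association and dissociation
rates (k_a, k_d).  Uncertainty comes from a cell-level bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .telegraph import (
    RateParams,
    fano_factor,
    mean_expression,
    moments_from_counts,
)

COUNT_COLUMNS = ["cell_id", "length_um", "mrna_count"]

#: default single-copy cell-length gate in micrometres
LENGTH_GATE = (1.73, 2.16)

#: divisor of the mean in the RNAP-variability Fano correction
FANO_CORRECTION_DIVISOR = 10.0


@dataclass
class CountTable:
    """Per-cell records (cell_id, length_um, mrna_count) for one strain."""

    df: pd.DataFrame
    operator_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in COUNT_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        if (self.df["mrna_count"] < 0).any():
            raise ValueError("mrna_count must be >= 0")
        if (self.df["length_um"] <= 0).any():
            raise ValueError("length_um must be > 0")

    @property
    def counts(self) -> np.ndarray:
        return self.df["mrna_count"].to_numpy(dtype=float)

    @property
    def lengths(self) -> np.ndarray:
        return self.df["length_um"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.df)

    def moments(self):
        return moments_from_counts(self.counts)


@dataclass
class DecaySeries:
    """Relative mRNA level after transcription halt at t = 0.

    ``levels`` are relative to the t = 0 sample (level(0) = 1 by
    convention); times in minutes, strictly increasing.
    """

    times: np.ndarray
    levels: np.ndarray
    replicate_id: str = "rep0"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.levels.shape:
            raise ValueError("times and levels must be matching 1-D arrays")
        if (self.times < 0).any() or (np.diff(self.times) <= 0).any():
            raise ValueError("times must be non-negative and strictly increasing")
        if (self.levels <= 0).any():
            raise ValueError("levels must be > 0")


@dataclass
class GammaFit:
    """Pooled log-linear degradation-rate fit."""

    gamma: float
    se: float
    per_replicate: dict[str, float]
    valid: bool


@dataclass
class RateEstimate:
    """Point estimates of (k_a, k_d) with bootstrap percentile intervals.

    When the moments are infeasible for the model (no repression, or a
    corrected Fano factor at/below the Poisson limit) ``feasible`` is False
    and ``reason`` carries a code; ``k_ratio`` = k_a/k_d may still be set
    from the mean alone in the fast-switching case.
    """

    k_a: float | None
    k_d: float | None
    k_ratio: float | None
    feasible: bool
    reason: str = "ok"
    ci_ka_lo: float | None = None
    ci_ka_hi: float | None = None
    ci_kd_lo: float | None = None
    ci_kd_hi: float | None = None
    sd_ka: float | None = None
    sd_kd: float | None = None
    n_bootstrap: int = 0
    infeasible_fraction: float = 0.0
    unstable: bool = False

    def to_json_dict(self) -> dict:
        return {
            "k_a": self.k_a,
            "k_d": self.k_d,
            "k_ratio": self.k_ratio,
            "feasible": self.feasible,
            "reason": self.reason,
            "ci": {
                "k_a": [self.ci_ka_lo, self.ci_ka_hi],
                "k_d": [self.ci_kd_lo, self.ci_kd_hi],
                "percentiles": [10, 90],
            },
            "bootstrap_sd": {"k_a": self.sd_ka, "k_d": self.sd_kd},
            "n_bootstrap": self.n_bootstrap,
            "infeasible_fraction": self.infeasible_fraction,
            "unstable": self.unstable,
        }


def correct_fano(fano: float, mu: float, divisor: float = FANO_CORRECTION_DIVISOR) -> float:
    """Corrected Fano factor F_c = F - mu/divisor (default divisor 10).

    Removes the contribution of RNA-polymerase copy-number variability to
    the measured Fano factor.  May fall at or below 1; downstream inversion
    then flags infeasibility rather than clamping.
    """
    if fano <= 0:
        raise ValueError("fano must be > 0")
    if mu < 0:
        raise ValueError("mu must be >= 0")
    return fano - mu / divisor


def estimate_r(mu_delta_lacI: float, gamma: float) -> float:
    """Basal transcription rate from the repressor-deletion mean: r = mu * gamma."""
    if mu_delta_lacI <= 0 or gamma <= 0:
        raise ValueError("mu_delta_lacI and gamma must be > 0")
    return mu_delta_lacI * gamma


def fit_degradation_rate(series: list[DecaySeries] | DecaySeries) -> GammaFit:
    """Degradation rate from log-linear least squares, pooled over replicates.

    Fits log(level) = -gamma * t with zero intercept (the t = 0 sample
    defines level 1), unweighted.  A non-decaying series yields gamma <= 0
    and is flagged invalid.
    """
    if isinstance(series, DecaySeries):
        series = [series]
    if not series:
        raise ValueError("need at least one decay series")
    ts, ys, per_rep = [], [], {}
    for s in series:
        t, y = s.times, np.log(s.levels)
        ts.append(t)
        ys.append(y)
        denom = float(np.dot(t, t))
        per_rep[s.replicate_id] = -float(np.dot(t, y)) / denom if denom > 0 else np.nan
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    denom = float(np.dot(t, t))
    if denom <= 0 or t[t > 0].size < 1:
        raise ValueError("need at least two distinct time points")
    gamma = -float(np.dot(t, y)) / denom
    resid = y + gamma * t
    dof = max(1, t.size - 1)
    se = math.sqrt(float(np.dot(resid, resid)) / dof / denom)
    valid = gamma > 0
    if not valid:
        import warnings

        warnings.warn("decay series is non-decreasing; gamma estimate invalid")
    return GammaFit(gamma=gamma, se=se, per_replicate=per_rep, valid=valid)


def _invert_closed_form(mu: float, fano_c: float, r: float, gamma: float):
    """Algebraic inversion of the stationary mean and Fano factor.

    With p_on = mu*gamma/r and s = k_a + k_d, the Fano expression gives
    s = r*(1 - p_on)/(F_c - 1) - gamma, then k_d = p_on*s, k_a = (1-p_on)*s.
    Returns (k_a, k_d, p_on, s) or a reason string on infeasibility.
    """
    p_on = mu * gamma / r
    if p_on >= 1.0:
        return None, None, p_on, None, "no_repression"
    if fano_c <= 1.0:
        return None, None, p_on, None, "fano_at_poisson_limit"
    s = r * (1.0 - p_on) / (fano_c - 1.0) - gamma
    if s <= 0:
        return None, None, p_on, s, "negative_switching_scale"
    return (1.0 - p_on) * s, p_on * s, p_on, s, "ok"


def _invert_numeric(mu: float, fano_c: float, r: float, gamma: float, x0) -> tuple[float, float]:
    """Root-find the 2x2 moment system in log-rate space (cross-check path)."""

    def resid(logx):
        ka, kd = np.exp(logx)
        p = RateParams(r, gamma, ka, kd)
        return [
            mean_expression(p) / mu - 1.0,
            (fano_factor(p) - 1.0) / (fano_c - 1.0) - 1.0,
        ]

    sol = least_squares(resid, np.log(x0), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ka, kd = np.exp(sol.x)
    return float(ka), float(kd)


def invert_moments(
    mu: float,
    fano_c: float,
    r: float,
    gamma: float,
    cross_check: bool = True,
    cross_check_rtol: float = 1e-8,
) -> RateEstimate:
    """Solve the stationary mean/Fano system for (k_a, k_d).

    The exact algebraic inversion is primary; with ``cross_check`` a
    numeric root-finder on the same 2x2 system must agree to
    ``cross_check_rtol`` relative.  Infeasible moment combinations return a
    structured failure (never an exception): ``no_repression`` when
    mu >= r/gamma, ``fano_at_poisson_limit`` when F_c <= 1 (k_ratio is then
    still reported from the mean), ``negative_switching_scale`` when the
    implied k_a + k_d is non-positive.
    """
    if mu <= 0 or r <= 0 or gamma <= 0:
        raise ValueError("mu, r and gamma must be > 0")
    ka, kd, p_on, s, reason = _invert_closed_form(mu, fano_c, r, gamma)
    if reason == "no_repression":
        return RateEstimate(None, None, None, False, reason)
    if reason != "ok":
        k_ratio = r / (mu * gamma) - 1.0
        return RateEstimate(None, None, k_ratio, False, reason)
    if cross_check:
        ka_n, kd_n = _invert_numeric(mu, fano_c, r, gamma, (ka, kd))
        if (
            abs(ka_n - ka) > cross_check_rtol * abs(ka)
            or abs(kd_n - kd) > cross_check_rtol * abs(kd)
        ):
            raise ArithmeticError(
                "closed-form and numeric inversions disagree: "
                f"({ka}, {kd}) vs ({ka_n}, {kd_n})"
            )
    return RateEstimate(ka, kd, ka / kd, True)


def _bootstrap_child_seed(seed: int, i: int) -> int:
    # fixed-increment substreams, kept below 2**31
    return (int(seed) + 1_000_003 * (i + 1)) % (2**31)


def bootstrap_rates(
    table: CountTable,
    r: float,
    gamma: float,
    n_boot: int = 1000,
    seed: int = 0,
    fano_divisor: float = FANO_CORRECTION_DIVISOR,
) -> RateEstimate:
    """Point estimate plus bootstrap percentile intervals for (k_a, k_d).

    The point estimate comes from the full table (mean + corrected Fano +
    algebraic inversion).  Each bootstrap replicate resamples cells with
    replacement and re-estimates; interval bounds are the 10th/90th
    nearest-rank percentiles of the feasible replicates, and the bootstrap
    standard deviation is reported alongside.  More than 50% infeasible
    replicates flags the estimate unstable.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if len(table) < 2:
        raise ValueError("count table must have at least 2 cells")
    counts = table.counts
    n = counts.size
    mom = moments_from_counts(counts)
    fc = correct_fano(mom.fano, mom.mu, fano_divisor)
    point = invert_moments(mom.mu, fc, r, gamma, cross_check=False)

    kas, kds = [], []
    n_bad = 0
    for i in range(n_boot):
        rng = np.random.default_rng(_bootstrap_child_seed(seed, i))
        res = counts[rng.integers(0, n, size=n)]
        mu_b = float(res.mean())
        if mu_b <= 0:
            n_bad += 1
            continue
        var_b = float(res.var(ddof=1))
        fc_b = correct_fano(var_b / mu_b, mu_b, fano_divisor)
        ka, kd, _, _, reason = _invert_closed_form(mu_b, fc_b, r, gamma)
        if reason != "ok":
            n_bad += 1
            continue
        kas.append(ka)
        kds.append(kd)

    est = replace(point)
    est.n_bootstrap = n_boot
    est.infeasible_fraction = n_bad / n_boot
    est.unstable = est.infeasible_fraction > 0.5
    if kas:
        kas_a, kds_a = np.array(kas), np.array(kds)
        est.ci_ka_lo, est.ci_ka_hi = (
            float(np.percentile(kas_a, 10, method="nearest")),
            float(np.percentile(kas_a, 90, method="nearest")),
        )
        est.ci_kd_lo, est.ci_kd_hi = (
            float(np.percentile(kds_a, 10, method="nearest")),
            float(np.percentile(kds_a, 90, method="nearest")),
        )
        est.sd_ka = float(kas_a.std(ddof=1)) if len(kas) > 1 else 0.0
        est.sd_kd = float(kds_a.std(ddof=1)) if len(kds) > 1 else 0.0
    return est


def occlusion_adjustment(
    k_a_exp: float, r: float, t_occlude_s: float = 1.0
) -> tuple[float, float]:
    """Availability factor and simulation association rate under occlusion.

    Each transcription event occludes the operator for ``t_occlude_s``
    seconds, so a fraction r*t_occlude/60 of the time is unavailable for
    binding (r in min^-1).  Returns (factor, k_a_sim) with
    factor = (60 - r*t_occlude)/60 and k_a_sim = k_a_exp / factor, the rate
    a simulator must use so the effective association rate matches the
    measured one.
    """
    occupied = r * t_occlude_s
    if occupied >= 60.0:
        raise ValueError("r * t_occlude >= 60 s/min: operator never available")
    if occupied < 0:
        raise ValueError("negative occlusion time")
    factor = (60.0 - occupied) / 60.0
    return factor, k_a_exp / factor


def fold_change_ddct(
    ct_target_treated: float,
    ct_ref_treated: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """RT-qPCR fold change by the 2^-ddCT method."""
    for v in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control):
        if not math.isfinite(v):
            raise ValueError("CT values must be finite")
    ddct = (ct_target_treated - ct_ref_treated) - (ct_target_control - ct_ref_control)
    return 2.0 ** (-ddct)


def filter_by_length(
    table: CountTable, lo: float = LENGTH_GATE[0], hi: float = LENGTH_GATE[1]
) -> CountTable:
    """Keep cells with lo <= length <= hi (inclusive), preserving order.

    The default gate selects cells carrying a single chromosomal copy of
    the reporter construct, suppressing gene-dosage variability.
    """
    if not lo < hi:
        raise ValueError("require lo < hi")
    keep = (table.df["length_um"] >= lo) & (table.df["length_um"] <= hi)
    return CountTable(table.df.loc[keep].reset_index(drop=True), table.operator_label)
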