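"""Moment inversion, auxiliary-rate estimation, bootstrap, and gating."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telekin import (
    CountTable,
    DecaySeries,
    RateParams,
    analytic_pmf,
    bootstrap_rates,
    correct_fano,
    estimate_r,
    fano_factor,
    filter_by_length,
    fit_degradation_rate,
    fold_change_ddct,
    invert_moments,
    mean_expression,
    occlusion_adjustment,
)
from telekin.synth import generate_decay_series, generate_population


def make_table(counts, lengths=None):
    counts = np.asarray(counts, dtype=float)
    lengths = np.full(counts.size, 1.9) if lengths is None else np.asarray(lengths)
    return CountTable(
        pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(counts.size)],
                "length_um": lengths,
                "mrna_count": counts,
            }
        )
    )


@pytest.mark.parametrize(
    "fano,mu,expected",
    [(2.0, 5.0, 1.5), (3.7, 0.0, 3.7), (1.05, 1.0, 0.95)],
)
def test_correct_fano(fano, mu, expected):
    assert correct_fano(fano, mu) == pytest.approx(expected, rel=1e-12)


def test_correct_fano_custom_divisor():
    assert correct_fano(2.0, 5.0, divisor=20.0) == pytest.approx(1.75)


def test_estimate_r_reference_point():
    # mean of the repressor-deletion strain times gamma gives the printed rate
    assert estimate_r(31.14, 0.79) == pytest.approx(24.6, abs=0.01)
    assert estimate_r(10.0, 1.0) == 10.0


def test_estimate_r_roundtrip_with_forward_model():
    p = RateParams(17.3, 0.9, 0.0, 1.0)
    assert estimate_r(mean_expression(p), p.gamma) == pytest.approx(p.r, rel=1e-12)


def test_degradation_fit_exact_on_noiseless_series():
    t = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
    fit = fit_degradation_rate(DecaySeries(t, np.exp(-0.79 * t)))
    assert fit.gamma == pytest.approx(0.79, rel=1e-12)
    assert fit.valid
    assert fit.se == pytest.approx(0.0, abs=1e-12)


def test_degradation_fit_flags_constant_series():
    t = np.array([0.0, 2.0, 4.0])
    with pytest.warns(UserWarning):
        fit = fit_degradation_rate(DecaySeries(t, np.ones_like(t)))
    assert not fit.valid or fit.gamma <= 0


def test_degradation_fit_calibration_under_noise():
    """Three replicates at 10% multiplicative noise recover gamma within
    10% in at least 95% of repetitions."""
    ok = 0
    n_rep = 200
    for rep in range(n_rep):
        series = generate_decay_series(0.79, noise_sd=0.1, n_replicates=3, seed=rep)
        fit = fit_degradation_rate(series)
        if abs(fit.gamma - 0.79) <= 0.1 * 0.79:
            ok += 1
    assert ok / n_rep >= 0.95


def test_invert_moments_roundtrip_slow_operator():
    est = invert_moments(1.7688679, 6.9258557, r=25.0, gamma=0.8)
    assert est.feasible
    assert est.k_a == pytest.approx(3.0, rel=1e-5)
    assert est.k_d == pytest.approx(0.18, rel=1e-5)


def test_invert_moments_roundtrip_reference_operator(osym_params):
    mu = mean_expression(osym_params)
    fano = fano_factor(osym_params)
    est = invert_moments(mu, fano, r=osym_params.r, gamma=osym_params.gamma)
    assert est.k_a == pytest.approx(9.79, rel=1e-8)
    assert est.k_d == pytest.approx(0.10, rel=1e-8)
    assert est.k_ratio == pytest.approx(97.9, rel=1e-8)


@pytest.mark.parametrize("r_t,ka_t,kd_t", [
    (r_t, ka_t, kd_t)
    for r_t in (2.0, 8.0, 30.0)
    for ka_t in (0.2, 2.0, 20.0)
    for kd_t in (0.05, 0.5, 5.0)
])
def test_invert_moments_roundtrips_forward_model(r_t, ka_t, kd_t):
    """Closed form inverts the forward moments exactly, and agrees with the
    numeric root-finder, over a broad feasible grid."""
    p = RateParams(r_t, 1.0, ka_t, kd_t)
    est = invert_moments(mean_expression(p), fano_factor(p), p.r, p.gamma,
                         cross_check=True, cross_check_rtol=1e-8)
    assert est.feasible
    assert est.k_a == pytest.approx(ka_t, rel=1e-8)
    assert est.k_d == pytest.approx(kd_t, rel=1e-8)


def test_invert_moments_no_repression_boundary():
    est = invert_moments(25.0 / 0.8, 3.0, r=25.0, gamma=0.8)
    assert not est.feasible
    assert est.reason == "no_repression"
    assert est.k_a is None and est.k_d is None


def test_invert_moments_fast_limit_keeps_ratio():
    est = invert_moments(2.0, 0.95, r=10.0, gamma=1.0)
    assert not est.feasible
    assert est.reason == "fano_at_poisson_limit"
    assert est.k_ratio == pytest.approx(10.0 / 2.0 - 1.0)


def test_invert_moments_negative_switching_scale():
    # F_c large enough that the implied k_a + k_d would be negative
    est = invert_moments(1.0, 50.0, r=10.0, gamma=1.0)
    assert not est.feasible
    assert est.reason == "negative_switching_scale"


@settings(max_examples=30, deadline=None, derandomize=True)
@given(step=st.floats(min_value=0.05, max_value=2.0))
def test_invert_moments_monotone_in_fano(step):
    """At fixed mean, a larger corrected Fano factor means slower switching:
    the recovered k_a + k_d strictly decreases."""
    mu, r, gamma = 1.7688679, 25.0, 0.8
    lo = invert_moments(mu, 3.0, r, gamma, cross_check=False)
    hi = invert_moments(mu, 3.0 + step, r, gamma, cross_check=False)
    assert lo.feasible and hi.feasible
    assert hi.k_a + hi.k_d < lo.k_a + lo.k_d


@pytest.mark.parametrize(
    "args,factor,ka_sim",
    [
        ((9.79, 24.6, 1.0), 0.59, 16.593220),
        ((5.0, 12.0, 0.0), 1.0, 5.0),
    ],
)
def test_occlusion_adjustment(args, factor, ka_sim):
    f, k = occlusion_adjustment(*args)
    assert f == pytest.approx(factor, abs=1e-12)
    assert k == pytest.approx(ka_sim, rel=1e-6)


def test_occlusion_adjustment_saturation():
    with pytest.raises(ValueError):
        occlusion_adjustment(1.0, 30.0, 2.1)  # r*t = 63 s of every minute


@pytest.mark.parametrize(
    "cts,expected",
    [((20, 20, 20, 20), 1.0), ((18, 20, 20, 20), 4.0), ((21, 20, 20, 20), 0.5)],
)
def test_fold_change_ddct(cts, expected):
    assert fold_change_ddct(*cts) == pytest.approx(expected)


def test_filter_by_length_gate():
    table = make_table([1, 2, 3, 4], lengths=[1.5, 1.8, 2.0, 2.5])
    gated = filter_by_length(table)
    assert len(gated) == 2
    assert list(gated.df["mrna_count"]) == [2, 3]


def test_filter_by_length_identity_and_empty():
    table = make_table([5, 6], lengths=[1.9, 2.0])
    assert len(filter_by_length(table, 1.9, 2.0)) == 2  # inclusive bounds
    empty = make_table(np.empty(0), lengths=np.empty(0))
    assert len(filter_by_length(empty)) == 0


def test_bootstrap_point_estimate_seed_independent(osym_params):
    table = generate_population(osym_params, 3000, seed=11)
    a = bootstrap_rates(table, osym_params.r, osym_params.gamma, n_boot=50, seed=1)
    b = bootstrap_rates(table, osym_params.r, osym_params.gamma, n_boot=50, seed=2)
    assert a.k_a == b.k_a and a.k_d == b.k_d  # point estimate ignores the seed
    assert (a.ci_ka_lo, a.ci_ka_hi) != (b.ci_ka_lo, b.ci_ka_hi)


def test_bootstrap_deterministic_under_seed(osym_params):
    table = generate_population(osym_params, 2000, seed=5)
    a = bootstrap_rates(table, osym_params.r, osym_params.gamma, n_boot=100, seed=9)
    b = bootstrap_rates(table, osym_params.r, osym_params.gamma, n_boot=100, seed=9)
    assert a == b


def test_bootstrap_single_replicate_interval_degenerates():
    # one bootstrap replicate: both percentile bounds collapse onto it
    rng = np.random.default_rng(3)
    counts = analytic_pmf(RateParams(10, 1, 2, 0.5)).sample(500, rng)
    table = make_table(counts)
    est = bootstrap_rates(table, 10.0, 1.0, n_boot=1, seed=0)
    if est.ci_ka_lo is not None:
        assert est.ci_ka_lo == est.ci_ka_hi
        assert est.ci_kd_lo == est.ci_kd_hi


def test_bootstrap_recovery_and_coverage(osym_params):
    """Synthetic populations at the reference operating point: point
    estimates land within 15% of truth and the 10-90 percentile interval
    covers truth in most repeated syntheses (scaled-down study)."""
    n_cover_ka = 0
    n_synth = 12
    errs = []
    for i in range(n_synth):
        table = generate_population(osym_params, 5000, seed=1000 + i)
        est = bootstrap_rates(table, osym_params.r, osym_params.gamma,
                              n_boot=200, seed=i)
        assert est.feasible
        errs.append(abs(est.k_a - 9.79) / 9.79)
        if est.ci_ka_lo <= 9.79 <= est.ci_ka_hi:
            n_cover_ka += 1
    assert np.median(errs) <= 0.15
    assert n_cover_ka / n_synth >= 0.7  # 80% nominal, small-sample slack
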