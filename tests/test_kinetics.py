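import math
import warnings

import numpy as np
import pytest

from pigmentox.dataio import KineticSeries, SampleMeta, ValidationError
from pigmentox.kinetics import (
    DecayResults,
    FirstOrderDecay,
    FitError,
    SigmoidAccumulation,
    SigmoidResults,
    aggregate_replicates,
    fit_decay,
    fit_sigmoid,
    half_life,
    induction_time,
    inflection_point,
    sigmoid_value,
)

LN2 = math.log(2.0)


def _series(times, values, pH=2.0, analyte="anthocyanin", rep=1, dose=0.73):
    meta = SampleMeta(sample_id="s", pH=pH, extract_dose=dose, replicate=rep)
    return KineticSeries(meta=meta, analyte=analyte, times=np.asarray(times, float),
                        values=np.asarray(values, float))


# ---------------------------------------------------------------------------
# independent numeric oracles
# ---------------------------------------------------------------------------

def _logistic(c0, cmax, k, t):
    return cmax / (1.0 + ((cmax - c0) / c0) * np.exp(-k * t))


def _mp_logistic(c0, cmax, k):
    """High-precision logistic curve evaluator (mpmath, 40 digits)."""
    import mpmath as mp

    mp.mp.dps = 40
    c0, cmax, k = mp.mpf(repr(c0)), mp.mpf(repr(cmax)), mp.mpf(repr(k))
    A = (cmax - c0) / c0
    return mp, (lambda t: cmax / (1 + A * mp.e**(-k * t))), c0, cmax, k


def _num_inflection(c0, cmax, k, *, _cache={}):
    """Bisection on the sign change of a finite-difference second derivative.

    Runs in 40-digit arithmetic so that the O(h²) central-difference bias
    and rounding noise stay far below the 1e-9 comparison tolerance.  The
    bracket is located from the curve itself: the rise is convex below and
    concave above the half-maximum, so the 30%/70%-of-maximum crossing
    times straddle the inflection.
    """
    mp, f, _, cmaxm, km = _mp_logistic(c0, cmax, k)
    h = mp.mpf("1e-8") / km

    def d2(t):
        return f(t + h) - 2 * f(t) + f(t - h)  # sign of f'' (dropping /h²)

    def crossing(frac):
        level = frac * cmaxm
        lo, hi = mp.mpf(0), mp.mpf(1)
        while f(lo) > level:
            lo = 2 * lo - 1
        while f(hi) < level:
            hi = 2 * hi + 1
        for _ in range(140):
            mid = (lo + hi) / 2
            if f(mid) < level:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2

    lo, hi = crossing(mp.mpf("0.3")), crossing(mp.mpf("0.7"))
    assert d2(lo) > 0 > d2(hi), "second derivative must change sign on the bracket"
    for _ in range(120):
        mid = (lo + hi) / 2
        if d2(mid) > 0:
            lo = mid
        else:
            hi = mid
    return float((lo + hi) / 2)


def _num_slope(c0, cmax, k, t):
    """High-precision central difference of the curve at t."""
    mp, f, *_ = _mp_logistic(c0, cmax, k)
    km = mp.mpf(repr(k))
    h = mp.mpf("1e-10") / km
    tm = mp.mpf(repr(t))
    return float((f(tm + h) - f(tm - h)) / (2 * h))


def _num_induction(c0, cmax, k):
    """Root of the tangent line constructed entirely numerically."""
    t_star = _num_inflection(c0, cmax, k)
    slope = _num_slope(c0, cmax, k, t_star)
    c_at = _logistic(c0, cmax, k, t_star)
    return t_star - c_at / slope


# ---------------------------------------------------------------------------
# curve evaluation
# ---------------------------------------------------------------------------

def test_sigmoid_starts_at_c0_and_saturates():
    assert sigmoid_value((1.0, 100.0, 1.0), 0.0) == pytest.approx(1.0, rel=1e-12)
    assert sigmoid_value((1.0, 100.0, 1.0), 100.0) == pytest.approx(100.0, rel=1e-9)


def test_sigmoid_passes_half_maximum_at_inflection():
    assert sigmoid_value((1.0, 100.0, 1.0), math.log(99.0)) == pytest.approx(50.0, rel=1e-12)


def test_sigmoid_strictly_increasing():
    t = np.linspace(0.0, 30.0, 400)
    c = sigmoid_value((2.0, 500.0, 0.7), t)
    assert np.all(np.diff(c) > 0)


@pytest.mark.parametrize("params", [(0.0, 100.0, 1.0), (-1.0, 100.0, 1.0), (5.0, 5.0, 1.0), (5.0, 4.0, 1.0)])
def test_sigmoid_rejects_inadmissible_parameters(params):
    with pytest.raises(ValueError):
        sigmoid_value(params, 1.0)


# ---------------------------------------------------------------------------
# half-life
# ---------------------------------------------------------------------------

def test_half_life_of_fastest_degradation_rate():
    # k = 1.44 day⁻¹ is the fastest pigment-loss rate in the study
    assert round(half_life(1.44), 2) == 0.48


def test_half_life_identity_and_scaling():
    assert half_life(LN2) == pytest.approx(1.0, rel=1e-12)
    assert half_life(2.88) == pytest.approx(0.2407, abs=5e-5)
    assert half_life(2.88) == pytest.approx(half_life(1.44) / 2.0, rel=1e-12)


def test_half_life_requires_positive_rate():
    with pytest.raises(ValueError):
        half_life(0.0)


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def test_decay_fit_recovers_noiseless_parameters_exactly():
    t = np.arange(0.0, 6.0)
    fit = FirstOrderDecay(t, 10.0 * np.exp(-0.5 * t)).fit()
    assert fit.C0_hat == pytest.approx(10.0, abs=1e-8)
    assert fit.k_hat == pytest.approx(0.5, abs=1e-8)
    assert fit.t_half == pytest.approx(1.3863, abs=5e-5)
    assert fit.converged


def test_decay_fit_constant_series_pins_rate_at_zero():
    t = np.arange(0.0, 6.0)
    with pytest.warns(RuntimeWarning, match="pinned"):
        fit = FirstOrderDecay(t, np.full(6, 7.0)).fit()
    assert fit.k_hat == 0.0
    assert fit.C0_hat == pytest.approx(7.0, abs=1e-6)
    assert math.isinf(fit.t_half)
    assert fit.k_at_bound


def test_decay_fit_rejects_all_zero_series():
    with pytest.raises(FitError, match="degenerate"):
        FirstOrderDecay(np.arange(3.0), np.zeros(3)).fit()


def test_decay_fit_requires_three_points():
    with pytest.raises(FitError):
        FirstOrderDecay(np.arange(2.0), np.ones(2))


def test_decay_halflife_rate_identity_holds_for_any_fit():
    rng = np.random.default_rng(11)
    t = np.arange(0.0, 8.0)
    for _ in range(20):
        v = np.clip(24.0 * np.exp(-1.44 * t) + rng.normal(0, 1.0, t.size), 0, None)
        fit = FirstOrderDecay(t, v).fit()
        if fit.k_hat > 0:
            assert fit.t_half * fit.k_hat == pytest.approx(LN2, rel=1e-12)


def test_decay_fit_noisy_recovery_matches_grid_search_oracle():
    """Pooled noisy fit recovers k within 10%; NLS beats a dense RSS grid."""
    rng = np.random.default_rng(42)
    t1 = np.arange(0.0, 8.0)
    t = np.tile(t1, 4)
    v = np.clip(24.0 * np.exp(-1.44 * t) + rng.normal(0, 1.0, t.size), 0, None)
    fit = FirstOrderDecay(t, v).fit()
    assert fit.k_hat == pytest.approx(1.44, rel=0.10)

    # independent oracle: dense grid over (C0, k) minimising RSS
    C0s = np.linspace(15.0, 35.0, 161)
    ks = np.linspace(0.5, 3.0, 401)
    rss = ((C0s[:, None, None] * np.exp(-ks[None, :, None] * t[None, None, :]) - v) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    assert fit.k_hat == pytest.approx(ks[j], abs=2 * (ks[1] - ks[0]))
    assert fit.rss <= rss[i, j] + 1e-9


# ---------------------------------------------------------------------------
# sigmoid fitting
# ---------------------------------------------------------------------------

def test_sigmoid_fit_recovers_noiseless_parameters():
    t = np.arange(0.0, 15.0)
    fit = SigmoidAccumulation(t, _logistic(1.0, 100.0, 1.0, t)).fit()
    assert fit.c0_hat == pytest.approx(1.0, rel=1e-6)
    assert fit.cmax_hat == pytest.approx(100.0, rel=1e-6)
    assert fit.k_hat == pytest.approx(1.0, rel=1e-6)
    assert fit.rss == pytest.approx(0.0, abs=1e-12)
    assert fit.converged


def test_sigmoid_fit_high_start_series_has_no_induction_phase():
    # hydroperoxide-like pattern at the most acidic pH: large initial level,
    # so the inflection tangent crosses zero left of the origin
    t = np.arange(0.0, 15.0)
    fit = SigmoidAccumulation(t, _logistic(67.0, 300.0, 4.0, t)).fit()
    assert fit.converged
    assert fit.t_ind is None


def test_sigmoid_fit_noisy_recovery_within_15_percent():
    """Recovery under study-like noise: σ = 25 µM, 10 timepoints × 4 replicates.

    cmax and k are well identified and must land within 15% in every
    realization; c0 (5 µM, far below the noise SD) is only weakly
    identified per realization, so its 15% check applies to the
    seed-averaged estimate.
    """
    days = np.array([0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 12.0, 15.0, 18.0, 21.0])
    t = np.tile(days, 4)
    estimates = []
    for seed in range(25):
        rng = np.random.default_rng(seed)
        v = np.clip(_logistic(5.0, 1000.0, 0.9, t) + rng.normal(0, 25.0, t.size), 0, None)
        fit = SigmoidAccumulation(t, v).fit()
        assert fit.cmax_hat == pytest.approx(1000.0, rel=0.15)
        assert fit.k_hat == pytest.approx(0.9, rel=0.15)
        estimates.append([fit.c0_hat, fit.cmax_hat, fit.k_hat])
    mean = np.mean(estimates, axis=0)
    assert mean[0] == pytest.approx(5.0, rel=0.15)
    assert mean[1] == pytest.approx(1000.0, rel=0.15)
    assert mean[2] == pytest.approx(0.9, rel=0.15)


def test_sigmoid_fit_flat_noise_flagged_non_converged():
    rng = np.random.default_rng(3)
    t = np.arange(0.0, 10.0)
    fit = SigmoidAccumulation(t, 50.0 + rng.normal(0, 0.5, t.size)).fit()
    assert not fit.converged
    assert fit.t_ind is None and fit.t_star is None


# ---------------------------------------------------------------------------
# inflection point and induction time vs numeric oracles
# ---------------------------------------------------------------------------

def test_inflection_closed_form_example():
    t_star, c_at, slope = inflection_point((1.0, 100.0, 1.0))
    assert t_star == pytest.approx(math.log(99.0), rel=1e-12)
    assert c_at == pytest.approx(50.0, rel=1e-12)
    assert slope == pytest.approx(25.0, rel=1e-12)


def test_inflection_at_origin_for_symmetric_start():
    t_star, c_at, _ = inflection_point((50.0, 100.0, 2.0))
    assert t_star == 0.0
    assert c_at == 50.0


def test_inflection_value_is_half_maximum_always():
    rng = np.random.default_rng(5)
    for _ in range(50):
        c0 = rng.uniform(0.1, 50.0)
        cmax = c0 * rng.uniform(1.1, 100.0)
        k = rng.uniform(0.05, 10.0)
        _, c_at, _ = inflection_point((c0, cmax, k))
        assert c_at / cmax == pytest.approx(0.5, rel=1e-12)


def test_induction_closed_form_example():
    assert induction_time((1.0, 100.0, 1.0)) == pytest.approx(math.log(99.0) - 2.0, rel=1e-12)


def test_induction_boundary_ratio_returns_none():
    # cmax/c0 = e² + 1 puts the tangent intercept exactly at the origin
    c0 = 3.0
    cmax = c0 * (math.e**2 + 1.0)
    assert induction_time((c0, cmax, 1.0)) is None


def test_induction_none_for_high_start():
    assert induction_time((67.0, 300.0, 4.0)) is None


def test_closed_forms_agree_with_numeric_oracle_on_random_triples():
    """t*, slope and t_ind match a finite-difference + bisection construction
    to 1e-9 over random admissible parameter draws."""
    rng = np.random.default_rng(123)
    n_checked = 0
    for _ in range(200):
        c0 = 10.0 ** rng.uniform(-2, 2)
        cmax = c0 * (1.0 + 10.0 ** rng.uniform(-1, 4))
        k = 10.0 ** rng.uniform(-1.5, 1.0)
        t_star, c_at, slope = inflection_point((c0, cmax, k))
        tol = 1e-9 * max(1.0, abs(t_star), 2.0 / k)
        assert _num_inflection(c0, cmax, k) == pytest.approx(t_star, abs=tol)
        assert _num_slope(c0, cmax, k, t_star) == pytest.approx(slope, rel=1e-9)
        t_ind = induction_time((c0, cmax, k))
        t_ind_num = _num_induction(c0, cmax, k)
        if t_ind is None:
            assert t_ind_num <= tol
        else:
            assert t_ind_num == pytest.approx(t_ind, abs=tol)
            n_checked += 1
    assert n_checked > 20  # the draw covers both regimes


def test_tangent_line_vanishes_at_induction_time():
    """Defining property: the inflection tangent evaluates to 0 at t_ind."""
    rng = np.random.default_rng(9)
    for _ in range(200):
        c0 = 10.0 ** rng.uniform(-2, 1)
        cmax = c0 * 10.0 ** rng.uniform(1.0, 4)
        k = 10.0 ** rng.uniform(-1, 1)
        t_ind = induction_time((c0, cmax, k))
        if t_ind is None:
            continue
        t_star, c_at, slope = inflection_point((c0, cmax, k))
        tangent_at_tind = c_at + slope * (t_ind - t_star)
        assert abs(tangent_at_tind) <= 1e-9 * cmax


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=200, derandomize=True)
@given(
    c0=st.floats(0.01, 100.0),
    ratio=st.floats(1.01, 1e4),
    k=st.floats(0.02, 15.0),
)
def test_sigmoid_invariants_hold_for_any_admissible_parameters(c0, ratio, k):
    """c(0) = c0, c(∞) → cmax, strict monotonicity, inflection at cmax/2,
    and a tangent that vanishes at t_ind whenever one exists."""
    cmax = c0 * ratio
    assert sigmoid_value((c0, cmax, k), 0.0) == pytest.approx(c0, rel=1e-9)
    t_star0 = math.log((cmax - c0) / c0) / k
    assert sigmoid_value((c0, cmax, k), t_star0 + 50.0 / k) == pytest.approx(cmax, rel=1e-9)
    # strict increase checked before float64 saturation at the plateau
    t = np.linspace(0.0, max(t_star0 + 10.0 / k, 1.0), 50)
    assert np.all(np.diff(sigmoid_value((c0, cmax, k), t)) > 0)
    t_star, c_at, slope = inflection_point((c0, cmax, k))
    assert c_at == pytest.approx(cmax / 2.0, rel=1e-12)
    assert slope > 0
    t_ind = induction_time((c0, cmax, k))
    if t_ind is not None:
        assert 0.0 < t_ind < t_star
        assert abs(c_at + slope * (t_ind - t_star)) <= 1e-9 * cmax


def test_monotonicity_in_rate_constant():
    ks = np.linspace(0.3, 5.0, 20)
    t_inds = [induction_time((1.0, 1000.0, k)) for k in ks]
    t_halves = [half_life(k) for k in ks]
    assert all(a > b for a, b in zip(t_inds, t_inds[1:]))
    assert all(a > b for a, b in zip(t_halves, t_halves[1:]))


# ---------------------------------------------------------------------------
# replicate aggregation
# ---------------------------------------------------------------------------

def _decay_fit(k, meta=None):
    return DecayResults(C0_hat=24.0, k_hat=k, rss=0.1, n_obs=9, converged=True,
                        meta=meta or SampleMeta("s", 2.0, 0.73, replicate=1))


def test_aggregate_identical_fits_zero_sd():
    agg = aggregate_replicates([_decay_fit(1.44), _decay_fit(1.44)])
    assert agg["k_hat_sd"] == 0.0
    assert agg["t_half_sd"] == 0.0


def test_aggregate_mean_halflife_differs_from_inverted_mean_rate():
    """Jensen gap: mean of per-replicate half-lives ≠ ln2 / mean(k)."""
    agg = aggregate_replicates([_decay_fit(1.0), _decay_fit(2.0)])
    assert agg["t_half_mean"] == pytest.approx((LN2 / 1.0 + LN2 / 2.0) / 2.0, abs=5e-5)
    assert agg["t_half_mean"] == pytest.approx(0.5199, abs=5e-5)
    assert agg["t_half_of_mean_k"] == pytest.approx(0.4621, abs=5e-5)
    assert agg["t_half_mean"] != pytest.approx(agg["t_half_of_mean_k"], abs=1e-3)


def test_aggregate_rejects_singleton_and_mixed_conditions():
    with pytest.raises(ValidationError):
        aggregate_replicates([_decay_fit(1.0)])
    other = _decay_fit(1.0, meta=SampleMeta("s", 3.0, 0.73, replicate=2))
    with pytest.raises(ValidationError, match="mixed conditions"):
        aggregate_replicates([_decay_fit(1.0), other])


def test_aggregate_sigmoid_excludes_absent_induction_times():
    meta = SampleMeta("s", 2.0, 0.0, replicate=1)
    with_ind = SigmoidResults(c0_hat=1.0, cmax_hat=1000.0, k_hat=1.0, rss=0.1,
                              n_obs=9, converged=True, meta=meta, analyte="LOOH")
    without = SigmoidResults(c0_hat=67.0, cmax_hat=300.0, k_hat=4.0, rss=0.1,
                             n_obs=9, converged=True, meta=meta, analyte="LOOH")
    agg = aggregate_replicates([with_ind, without])
    assert agg["n_t_ind"] == 1
    assert agg["t_ind_mean"] == pytest.approx(with_ind.t_ind)
    agg2 = aggregate_replicates([without, without])
    assert agg2["t_ind_mean"] is None


def test_results_plot_shows_data_and_fit():
    import matplotlib

    matplotlib.use("Agg")
    t = np.arange(0.0, 15.0)
    ax = SigmoidAccumulation(t, _logistic(1.0, 100.0, 1.0, t)).fit().plot()
    assert len(ax.lines) >= 2  # observations, curve (+ tangent)
    ax2 = FirstOrderDecay(t[:8], 24.0 * np.exp(-1.44 * t[:8])).fit().plot()
    assert ax2.get_xlabel() == "time (days)"


def test_functional_facade_matches_model_classes():
    t = np.arange(0.0, 9.0)
    s = _series(t, 24.0 * np.exp(-1.44 * t))
    assert fit_decay(s).k_hat == pytest.approx(1.44, abs=1e-8)
    s2 = _series(t, _logistic(1.0, 100.0, 1.0, t), analyte="LOOH")
    assert fit_sigmoid(s2).k_hat == pytest.approx(1.0, rel=1e-6)
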