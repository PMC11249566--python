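"""Estimating equation solve, sandwich variance, curves, stepwise."""

import warnings

import numpy as np
import pytest

from dynrmtl import (
    DynamicRMTLRegression,
    ExtrapolationWarning,
    SingularFitError,
    TimeBasis,
    TimeGrid,
    build_stacked_dataset,
    expand_design,
    fit_dynamic_rmtl,
    fit_static_rmtl,
)
from dynrmtl.examples import breast_cancer_model, example_patients


# ------------------------------------------------------------- expansion

def test_expand_design_full_quadratic():
    row = np.array([[1.0, 0.5]])
    out = expand_design(row, 2.0, TimeBasis.full(1, 2))
    np.testing.assert_allclose(out[0], [1, 2, 4, 0.5, 1, 2])


def test_expand_design_partial_mask_and_l_zero():
    mask = np.zeros((2, 3), dtype=bool)
    mask[0, 0] = True
    mask[1, 2] = True  # covariate keeps only its l^2 term
    basis = TimeBasis(mask)
    out = expand_design(np.array([[1.0, 3.0]]), 2.0, basis)
    np.testing.assert_allclose(out[0], [1.0, 12.0])
    out0 = expand_design(np.array([[1.0, 3.0]]), 0.0, TimeBasis.full(1, 2))
    np.testing.assert_allclose(out0[0], [1, 0, 0, 3, 0, 0])


def test_expand_design_dimension_mismatch():
    with pytest.raises(ValueError):
        expand_design(np.ones((2, 3)), 1.0, TimeBasis.full(1, 2))


# ------------------------------------------------------------------ fits

def test_intercept_only_equals_weighted_mean(uncensored_cohort_2k):
    time, status, _ = uncensored_cohort_2k
    m = fit_dynamic_rmtl(time, status, np.empty((time.size, 0)),
                         horizons=[1.0], degree=0)
    lost = np.where((status == 1) & (time < 1.0), 1.0 - time, 0.0)
    assert m.coef_[0] == pytest.approx(lost.mean(), abs=1e-12)


def test_two_group_no_censoring_equals_mean_difference(uncensored_cohort_2k):
    time, status, Z = uncensored_cohort_2k
    g = Z[:, 0]
    m = fit_static_rmtl(time, status, g[:, None], tau=1.0)
    lost = np.where((status == 1) & (time < 1.0), 1.0 - time, 0.0)
    diff = lost[g == 1].mean() - lost[g == 0].mean()
    assert m.coef_[1] == pytest.approx(diff, abs=1e-10)


def test_static_equals_single_horizon_dynamic(cohort_2k):
    time, status, Z = cohort_2k
    stat = fit_static_rmtl(time, status, Z, tau=1.2)
    dyn = fit_dynamic_rmtl(time, status, Z, horizons=[1.2], degree=0,
                           tau=1.2)
    np.testing.assert_allclose(stat.coef_, dyn.coef_, atol=1e-10)
    np.testing.assert_allclose(stat.covariance_, dyn.covariance_, atol=1e-10)


def test_fit_is_weighted_least_squares_optimum(cohort_2k):
    time, status, Z = cohort_2k
    grid = TimeGrid(np.linspace(0.2, 1.4, 12), 1.4)
    st_ = build_stacked_dataset(time, status, Z, grid)
    m = DynamicRMTLRegression(horizons=grid.horizons).fit(
        Z, np.column_stack([time, status]))
    X1 = np.column_stack([np.ones(st_.n_subjects), st_.covariates])
    Xe = expand_design(X1[st_.subject], st_.horizon, m.basis_)
    grad = Xe.T @ (st_.weight * (st_.lost_time - Xe @ m.coef_))
    assert np.linalg.norm(grad) / st_.subject.size < 1e-10


def test_sandwich_reduces_to_robust_variance_of_mean(uncensored_cohort_2k):
    time, status, _ = uncensored_cohort_2k
    m = fit_dynamic_rmtl(time, status, np.empty((time.size, 0)),
                         horizons=[1.0], degree=0)
    lost = np.where((status == 1) & (time < 1.0), 1.0 - time, 0.0)
    expected = np.sum((lost - lost.mean()) ** 2) / lost.size ** 2
    assert m.covariance_[0, 0] == pytest.approx(expected, rel=1e-10)


def test_singular_fit_names_collinear_columns(cohort_2k):
    time, status, Z = cohort_2k
    X = np.column_stack([Z, Z[:, 0]])  # exact duplicate
    with pytest.raises(SingularFitError, match="z"):
        fit_dynamic_rmtl(time, status, X, horizons=[0.5, 1.0])


def test_covariance_symmetric_psd(cohort_2k):
    time, status, Z = cohort_2k
    m = fit_dynamic_rmtl(time, status, Z, n_horizons=10)
    V = m.covariance_
    np.testing.assert_allclose(V, V.T, atol=1e-14)
    assert np.all(np.linalg.eigvalsh(V) > -1e-12)


# ----------------------------------------------------- curves and effects

def test_coefficient_curve_matches_published_formula():
    m = breast_cancer_model()
    est, _, _, _ = m.coefficient_curve("er_pos", 4.5)
    assert est == pytest.approx(0.291 - 0.141 * 4.5 + 0.005 * 4.5 ** 2,
                                abs=1e-12)
    assert round(est, 2) == -0.24  # reported as ~ -0.25 with rounded inputs
    # a covariate retaining only l^2 vanishes at l = 0 (extrapolated)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        est0, _, _, _ = m.coefficient_curve("t2", 0.0)
    assert est0 == 0.0


def test_realtime_effect_slopes():
    m = breast_cancer_model()
    assert m.realtime_effect("er_pos", 4.5) == pytest.approx(
        -0.141 + 2 * 0.005 * 4.5, abs=1e-12)
    # linear-only term: constant speed of accumulation
    assert m.realtime_effect("pr_pos", 4.5) == pytest.approx(-0.027)
    assert m.realtime_effect("pr_pos", 6.5) == pytest.approx(-0.027)
    # quadratic-only term at two horizons
    assert m.realtime_effect("t2", 5.0) == pytest.approx(2 * 0.006 * 5.0)


def test_curve_ci_width_grows_with_basis_norm(cohort_2k):
    time, status, Z = cohort_2k
    m = fit_dynamic_rmtl(time, status, Z, n_horizons=10)
    lo, hi = m.grid_.horizons[0], m.grid_.horizons[-1]
    _, se_mid, _, _ = m.coefficient_curve(0, (lo + hi) / 2)
    _, se_hi, _, _ = m.coefficient_curve(0, hi)
    assert se_hi > 0 and se_mid > 0


def test_wald_table_consistency(cohort_2k):
    time, status, Z = cohort_2k
    m = fit_dynamic_rmtl(time, status, Z, n_horizons=10)
    tab = m.wald_table()
    np.testing.assert_allclose(tab["z"], tab["coefficient"] / tab["se"])
    from scipy import stats
    np.testing.assert_allclose(tab["p"],
                               2 * stats.norm.sf(np.abs(tab["z"])))
    assert tab["variable"].iloc[0] == "Intercept"


# ------------------------------------------------------------- prediction

def test_predict_additive_in_covariates():
    m = breast_cancer_model()
    pats = example_patients()
    a = m.predict(pats.loc[["A"]], 10.0)[0]
    b = m.predict(pats.loc[["B"]], 10.0)[0]
    bcs_term = -0.003 * 100
    chemo_term = 0.160 - 0.092 * 10 + 0.004 * 100
    assert b - a == pytest.approx(bcs_term + chemo_term, abs=1e-12)


def test_all_reference_prediction_is_intercept_curve():
    m = breast_cancer_model()
    x0 = np.zeros((1, m.n_features_in_))
    for l in (3.0, 7.5):
        est, _, _, _ = m.coefficient_curve(0, l)
        assert m.predict(x0, l)[0] == pytest.approx(est, abs=1e-12)


def test_predict_vector_horizons_and_truncation():
    m = breast_cancer_model()
    pats = example_patients()
    out = m.predict(pats, [5.0, 10.0])
    assert out.shape == (3, 2)
    x = np.zeros((1, m.n_features_in_))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ExtrapolationWarning)
        raw = m.predict(x, 0.5)[0]
        clipped = m.predict(x, 0.5, truncate=True)[0]
    assert raw < 0 and clipped == 0.0


def test_extrapolation_warning_and_feature_mismatch(cohort_2k):
    time, status, Z = cohort_2k
    m = fit_dynamic_rmtl(time, status, Z, n_horizons=10)
    with pytest.warns(ExtrapolationWarning):
        m.predict(Z[:3], m.grid_.horizons[-1] + 1.0)
    with pytest.raises(ValueError, match="features"):
        m.predict(np.zeros((2, 5)), 1.0)


# --------------------------------------------------------------- stepwise

def test_stepwise_keeps_strong_effects(cohort_5k):
    time, status, Z = cohort_5k
    m = DynamicRMTLRegression(n_horizons=10, stepwise=True).fit(
        Z, np.column_stack([time, status]))
    assert m.basis_.mask[1].any() and m.basis_.mask[2].any()
    tab = m.wald_table()
    assert (tab["p"] <= 0.05).all() or len(tab) >= 3


def test_stepwise_no_removal_when_all_significant(cohort_5k):
    time, status, Z = cohort_5k
    full = DynamicRMTLRegression(n_horizons=8, degree=0).fit(
        Z, np.column_stack([time, status]))
    if (full.wald_table()["p"] > 0.05).any():
        pytest.skip("constant-basis fit not uniformly significant here")
    sw = DynamicRMTLRegression(n_horizons=8, degree=0, stepwise=True).fit(
        Z, np.column_stack([time, status]))
    np.testing.assert_array_equal(sw.basis_.mask, full.basis_.mask)


def test_static_interpretation_sign(cohort_5k):
    # both exposures lower the cause-1 RMTL: protective, negative signs
    time, status, Z = cohort_5k
    m = fit_static_rmtl(time, status, Z, tau=1.2)
    assert m.coef_[1] < 0 and m.coef_[2] < 0
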