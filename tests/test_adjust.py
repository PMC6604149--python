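import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tivadjust import (
    adjust_pcp,
    adjust_proportion,
    adjust_residuals,
    fit_covariate_regression,
    fit_pcp,
)
from tivadjust.adjust import DegenerateDesignError
from tivadjust.simulate import GeneratorSpec, generate_cohort

from .conftest import make_cohort, random_cohort


# --- proportion ---------------------------------------------------------


def test_proportion_hand_instance(atlas):
    cohort = make_cohort([1500.0], [1600.0], {"Amygdala_L": [7.5, 8.0]}, atlas=atlas)
    adj = adjust_proportion(cohort)
    assert adj.method == "proportion"
    assert adj.fit_params is None
    assert adj.table.data["Amygdala_L"].iloc[0] == pytest.approx(0.005, abs=1e-15)


def test_proportion_scale_invariance(atlas):
    a = make_cohort([1500.0], [1600.0], {"Amygdala_L": [7.5, 8.0]}, atlas=atlas)
    b = make_cohort([3000.0], [1600.0], {"Amygdala_L": [15.0, 8.0]}, atlas=atlas)
    va = adjust_proportion(a).table.data["Amygdala_L"].iloc[0]
    vb = adjust_proportion(b).table.data["Amygdala_L"].iloc[0]
    assert va == vb


def test_proportion_of_tiv_column_is_one(atlas):
    cohort = make_cohort(
        [1500.0, 1480.0], [1600.0, 1650.0],
        {"Amygdala_L": [1500.0, 1480.0, 1600.0, 1650.0]}, atlas=atlas,
    )
    adj = adjust_proportion(cohort)
    assert np.allclose(adj.table.data["Amygdala_L"], 1.0, rtol=0, atol=0)


# --- PCP ----------------------------------------------------------------


def test_pcp_base_invariance(toy_cohort):
    """The fitted exponent is the same in any logarithm base."""
    fits = fit_pcp(toy_cohort)
    x10 = np.log10(toy_cohort.tiv)
    for voi, b in zip(fits["voi"], fits["b"]):
        y10 = np.log10(toy_cohort.data[voi])
        slope10 = np.polyfit(x10, y10, 1)[0]
        assert b == pytest.approx(slope10, rel=1e-12)


def test_pcp_b1_reduces_to_proportion(toy_cohort):
    fits = fit_pcp(toy_cohort)
    fits["b"] = 1.0
    adj = adjust_pcp(toy_cohort, fits)
    prop = adjust_proportion(toy_cohort)
    assert np.allclose(adj.table.voi_matrix(), prop.table.voi_matrix(), rtol=1e-14)


def test_pcp_b0_returns_raw(toy_cohort):
    fits = fit_pcp(toy_cohort)
    fits["b"] = 0.0
    adj = adjust_pcp(toy_cohort, fits)
    assert np.allclose(adj.table.voi_matrix(), toy_cohort.voi_matrix(), rtol=1e-14)


def test_pcp_noiseless_adjusted_values_constant(atlas):
    """On exact power-law data with the true exponents, the PCP-adjusted
    value is the scale constant times the group factor, identical for all
    subjects in a group.  (With a non-zero group offset the *estimated*
    exponent absorbs part of the offset — TIV correlates with group — so
    the fits are supplied here rather than re-estimated.)"""
    names = atlas.names[:2]
    params = pd.DataFrame(
        {"voi": names, "c": [0.001, 0.004], "b": [0.863, 0.6], "sigma": 0.0,
         "delta": [0.0, 0.02]}
    )
    spec = GeneratorSpec(
        n_per_group=(10, 10), tiv_mean=(1480.0, 1610.0), tiv_sd=(77.0, 75.0),
        voi_params=params, seed=1,
    )
    cohort, _ = generate_cohort(spec, atlas)
    true_fits = params.rename(columns={})[["voi", "b"]].assign(intercept=np.log(params["c"]))
    adj = adjust_pcp(cohort, fits=true_fits)
    values = adj.table.voi_matrix()
    mask = cohort.comparison_mask()
    for j, (c, delta) in enumerate(zip(params["c"], params["delta"])):
        assert np.allclose(values[~mask, j], c, rtol=1e-9)
        assert np.allclose(values[mask, j], c * np.exp(delta), rtol=1e-9)
    # with delta = 0 everywhere, the re-estimated fit gives the same constancy
    null_spec = GeneratorSpec(
        n_per_group=(10, 10), tiv_mean=(1480.0, 1610.0), tiv_sd=(77.0, 75.0),
        voi_params=params.assign(delta=0.0), seed=1,
    )
    null_cohort, _ = generate_cohort(null_spec, atlas)
    refit = adjust_pcp(null_cohort)
    v = refit.table.voi_matrix()
    assert np.allclose(v, v.mean(axis=0), rtol=1e-9)


def test_pcp_zero_volume_instructs_exclusion(atlas):
    cohort = make_cohort([1500.0], [1600.0], {"Amygdala_L": [0.0, 8.0]}, atlas=atlas)
    with pytest.raises(ValueError, match="exclude"):
        fit_pcp(cohort)


def test_pcp_missing_fit_rejected(toy_cohort):
    fits = fit_pcp(toy_cohort).iloc[:1]
    with pytest.raises(KeyError, match="no power-law fit"):
        adjust_pcp(toy_cohort, fits)


# --- residuals ----------------------------------------------------------


def test_residuals_orthogonality_and_mean_preservation(null_cohort):
    cohort, _, _ = null_cohort
    adj = adjust_residuals(cohort)
    raw = cohort.voi_matrix()
    fixed = adj.table.voi_matrix()
    tiv_c = cohort.tiv - cohort.tiv.mean()
    cov = tiv_c @ (fixed - fixed.mean(axis=0)) / (cohort.n - 1)
    assert np.abs(cov).max() < 1e-10
    assert np.allclose(fixed.mean(axis=0), raw.mean(axis=0), rtol=1e-12)


def test_residuals_five_subject_hand_oracle(atlas):
    tiv = np.array([1400.0, 1450.0, 1500.0, 1550.0, 1600.0])
    voi = np.array([1.2, 1.4, 1.3, 1.6, 1.7])
    cohort = make_cohort(tiv[:2], tiv[2:], {"Amygdala_L": voi}, atlas=atlas)
    adj = adjust_residuals(cohort)
    # closed-form OLS: b = S_xy / S_xx on the whole sample
    xc = tiv - tiv.mean()
    b = (xc @ voi) / (xc @ xc)
    expected = voi - b * xc
    assert np.allclose(adj.table.data["Amygdala_L"], expected, rtol=1e-14)
    assert adj.fit_params["b"].iloc[0] == pytest.approx(b)
    assert adj.fit_params["tiv_mean"].iloc[0] == pytest.approx(1500.0)


def test_residuals_constant_tiv_rejected(atlas):
    cohort = make_cohort(
        [1500.0, 1500.0], [1500.0, 1500.0],
        {"Amygdala_L": [1.4, 1.5, 1.6, 1.7]}, atlas=atlas,
    )
    with pytest.raises(DegenerateDesignError):
        adjust_residuals(cohort)


# --- covariate regression ----------------------------------------------


@pytest.mark.parametrize("n_f,n_m,seed", [(3, 3, 0), (10, 12, 1), (25, 25, 2)])
def test_covariate_regression_matches_statsmodels(atlas, n_f, n_m, seed):
    """Closed-form normal equations agree with the reference OLS fitter."""
    rng = np.random.default_rng(seed)
    cohort = random_cohort(rng, n_f=n_f, n_m=n_m, n_voi=3, atlas=atlas)
    fit = fit_covariate_regression(cohort)
    X = sm.add_constant(
        np.column_stack([cohort.tiv, cohort.comparison_mask().astype(float)])
    )
    for _, row in fit.iterrows():
        model = sm.OLS(cohort.data[row["voi"]].to_numpy(), X).fit()
        assert row["b0"] == pytest.approx(model.params[0], rel=1e-10)
        assert row["b_tiv"] == pytest.approx(model.params[1], rel=1e-10)
        assert row["b_sex"] == pytest.approx(model.params[2], rel=1e-10, abs=1e-12)
        assert row["p_tiv"] == pytest.approx(model.pvalues[1], rel=1e-8)
        assert row["p_sex"] == pytest.approx(model.pvalues[2], rel=1e-8)
        assert row["r2"] == pytest.approx(model.rsquared, rel=1e-10)


def test_covariate_standardized_betas_equal_zscored_fit(atlas):
    rng = np.random.default_rng(7)
    cohort = random_cohort(rng, n_f=15, n_m=15, n_voi=2, atlas=atlas)
    fit = fit_covariate_regression(cohort)
    z = lambda v: (v - v.mean()) / v.std(ddof=1)
    Xz = sm.add_constant(
        np.column_stack([z(cohort.tiv), z(cohort.comparison_mask().astype(float))])
    )
    for _, row in fit.iterrows():
        model = sm.OLS(z(cohort.data[row["voi"]].to_numpy()), Xz).fit()
        assert row["beta_tiv"] == pytest.approx(model.params[1], rel=1e-10)
        assert row["beta_sex"] == pytest.approx(model.params[2], rel=1e-10, abs=1e-12)
    assert (fit["sr_tiv"].abs() <= 1).all() and (fit["sr_sex"].abs() <= 1).all()


def test_covariate_null_behavior(atlas):
    """When group is independent of TIV and volume, the sex coefficient is
    centred on zero and its p value is uniform over repetitions."""
    pvals, coefs = [], []
    for seed in range(120):
        rng = np.random.default_rng(seed)
        n = 15
        tiv = np.concatenate([rng.uniform(1400, 1700, n), rng.uniform(1400, 1700, n)])
        voi = 0.001 * tiv + rng.normal(0, 0.05, 2 * n)
        cohort = make_cohort(tiv[:n], tiv[n:], {"Amygdala_L": voi}, atlas=atlas)
        fit = fit_covariate_regression(cohort)
        pvals.append(fit["p_sex"].iloc[0])
        coefs.append(fit["b_sex"].iloc[0])
    assert abs(np.mean(pvals) - 0.5) < 0.08  # uniform p has mean 0.5
    assert abs(np.mean(coefs)) < 0.01
    assert 0.01 < np.mean(np.array(pvals) < 0.05) < 0.12


def test_covariate_pooled_sd_option(atlas):
    rng = np.random.default_rng(3)
    cohort = random_cohort(rng, n_f=12, n_m=12, n_voi=1, atlas=atlas)
    whole = fit_covariate_regression(cohort, d_sd="whole_sample")
    pooled = fit_covariate_regression(cohort, d_sd="pooled")
    assert whole["b_sex"].iloc[0] == pooled["b_sex"].iloc[0]
    assert whole["d_sex"].iloc[0] != pooled["d_sex"].iloc[0]


def test_covariate_degenerate_design(atlas):
    cohort = make_cohort(
        [1500.0, 1500.0], [1500.0, 1500.0],
        {"Amygdala_L": [1.4, 1.5, 1.6, 1.7]}, atlas=atlas,
    )
    with pytest.raises(DegenerateDesignError):
        fit_covariate_regression(cohort)
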