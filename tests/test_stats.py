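import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tivadjust import (
    adjust_residuals,
    cohens_d,
    d_confidence_interval,
    d_from_t,
    levene_test,
    slope_frequency_test,
    slope_outcome_correlation,
    tiv_regression,
    ttest_by_voi,
    ttest_from_summary,
)
from tivadjust.cohort import raw_dataset
from tivadjust.simulate import GeneratorSpec, generate_cohort

from .conftest import make_cohort, random_cohort


# --- summary-statistic entry points -------------------------------------


@pytest.mark.parametrize(
    ("summary", "t", "t_tol", "d", "ci"),
    [
        # TIV comparison of a matched pairing: near-identical groups
        ((1546.191, 75.397, 74, 1545.111, 77.372, 74), 0.086, 5e-3, 0.01, (-0.308, 0.336)),
        # education years, full samples: negligible difference (the published
        # t of 0.24 comes from unrounded means; the rounded summaries give 0.218)
        ((14.61, 2.21, 185, 14.56, 2.10, 171), 0.24, 0.03, 0.02, (-0.18, 0.23)),
        # age, full samples: small non-significant difference
        ((22.39, 3.04, 185, 21.64, 4.90, 171), 1.75, 5e-3, 0.186, (-0.02, 0.39)),
    ],
)
def test_pooled_t_from_printed_summaries(summary, t, t_tol, d, ci):
    res = ttest_from_summary(*summary)
    assert res["t"] == pytest.approx(t, abs=t_tol)
    assert res["d"] == pytest.approx(d, abs=5e-3)
    assert res["d_ci_low"] == pytest.approx(ci[0], abs=5e-3)
    assert res["d_ci_high"] == pytest.approx(ci[1], abs=5e-3)


def test_equal_means_give_zero_d_and_symmetric_ci():
    res = ttest_from_summary(10.0, 2.0, 30, 10.0, 2.0, 30)
    assert res["t"] == 0.0 and res["d"] == 0.0
    assert res["d_ci_low"] == pytest.approx(-res["d_ci_high"])


def test_d_from_t_identity_with_cohens_d():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.normal(0, 1, rng.integers(5, 30))
        b = rng.normal(0.3, 1.2, rng.integers(5, 30))
        t, _ = sps.ttest_ind(a, b, equal_var=True)
        d1 = d_from_t(t, len(a), len(b))
        d2 = cohens_d(a.mean(), b.mean(), a.std(ddof=1), b.std(ddof=1), len(a), len(b))
        assert d1 == pytest.approx(d2, rel=1e-12)
    assert d_from_t(0.0, 10, 10) == 0.0


def test_zero_pooled_sd_rejected():
    with pytest.raises(ZeroDivisionError):
        cohens_d(1.0, 2.0, 0.0, 0.0, 5, 5)


def test_noncentral_ci_brackets_d_and_matches_normal_to_first_order():
    lo_n, hi_n = d_confidence_interval(0.5, 100, 100, method="normal")
    lo_t, hi_t = d_confidence_interval(0.5, 100, 100, method="noncentral")
    assert lo_t < 0.5 < hi_t
    assert lo_n == pytest.approx(lo_t, abs=0.01)
    assert hi_n == pytest.approx(hi_t, abs=0.01)


# --- per-region t tests --------------------------------------------------


def test_identical_groups_give_null_outcome(atlas):
    values = [1.5, 1.6, 1.7]
    cohort = make_cohort(
        [1500.0, 1520.0, 1540.0], [1500.0, 1520.0, 1540.0],
        {"Amygdala_L": values + values}, atlas=atlas,
    )
    table = ttest_by_voi(raw_dataset(cohort))
    assert table["t"].iloc[0] == 0.0
    assert table["d"].iloc[0] == 0.0
    assert table["direction"].iloc[0] == "none"


def test_ttest_by_voi_matches_columnwise_scipy(atlas):
    rng = np.random.default_rng(12)
    cohort = random_cohort(rng, n_f=8, n_m=10, n_voi=4, atlas=atlas)
    table = ttest_by_voi(raw_dataset(cohort))
    mask = cohort.comparison_mask()
    for _, row in table.iterrows():
        v = cohort.data[row["voi"]].to_numpy()
        t, p = sps.ttest_ind(v[mask], v[~mask], equal_var=True)
        assert row["t"] == pytest.approx(t, rel=1e-12)
        assert row["p"] == pytest.approx(p, rel=1e-12)
        assert row["df"] == 16
        # d consistent with its own t (pooled-variance identity)
        assert row["d"] == pytest.approx(float(d_from_t(t, mask.sum(), (~mask).sum())), rel=1e-12)


def test_marginal_flag_between_alphas(atlas):
    rng = np.random.default_rng(1)
    cohort = random_cohort(rng, n_f=10, n_m=10, n_voi=5, atlas=atlas)
    table = ttest_by_voi(raw_dataset(cohort), alpha=0.05, marginal_alpha=0.99)
    assert ((table["p"] < 0.99) & ~table["significant"] == table["marginal"]).all()


def test_single_group_rejected(atlas):
    cohort = make_cohort([1500.0, 1520.0], [], {"Amygdala_L": [1.5, 1.6]}, atlas=atlas)
    with pytest.raises(Exception, match="group"):
        ttest_by_voi(raw_dataset(cohort))


# --- Levene -------------------------------------------------------------


def test_levene_identical_and_shifted_groups():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    f1, _ = levene_test(np.concatenate([a, a]), ["x"] * 4 + ["y"] * 4)
    assert f1 == pytest.approx(0.0, abs=1e-12)
    f2, _ = levene_test(np.concatenate([a, a + 5.0]), ["x"] * 4 + ["y"] * 4)
    assert f2 == pytest.approx(0.0, abs=1e-12)


def test_levene_equals_anova_on_absolute_deviations():
    rng = np.random.default_rng(5)
    a = rng.normal(0, 1, 12)
    b = rng.normal(0, 2.5, 15)
    f, p = levene_test(np.concatenate([a, b]), ["a"] * 12 + ["b"] * 15)
    f_ref, p_ref = sps.f_oneway(np.abs(a - a.mean()), np.abs(b - b.mean()))
    assert f == pytest.approx(f_ref, rel=1e-12)
    assert p == pytest.approx(p_ref, rel=1e-12)


# --- TIV regression ------------------------------------------------------


def test_tiv_regression_matches_linregress(atlas):
    rng = np.random.default_rng(8)
    cohort = random_cohort(rng, n_f=9, n_m=9, n_voi=3, atlas=atlas)
    table = tiv_regression(raw_dataset(cohort))
    for _, row in table.iterrows():
        ref = sps.linregress(cohort.tiv, cohort.data[row["voi"]])
        assert row["slope"] == pytest.approx(ref.slope, rel=1e-12)
        assert row["intercept"] == pytest.approx(ref.intercept, rel=1e-12)
        assert row["r2"] == pytest.approx(ref.rvalue**2, rel=1e-10)
        assert row["slope_p"] == pytest.approx(ref.pvalue, rel=1e-9)
        assert row["pct_variance"] == pytest.approx(100 * ref.rvalue**2, rel=1e-10)


def test_residual_adjusted_slopes_are_zero(null_cohort):
    cohort, _, _ = null_cohort
    table = tiv_regression(adjust_residuals(cohort))
    assert np.abs(table["slope"]).max() < 1e-12


def test_noiseless_proportional_raw_r2_is_one(atlas):
    params = pd.DataFrame(
        {"voi": atlas.names[:2], "c": [0.001, 0.003], "b": 1.0, "sigma": 0.0, "delta": 0.0}
    )
    spec = GeneratorSpec(
        n_per_group=(8, 8), tiv_mean=(1480.0, 1610.0), tiv_sd=(77.0, 75.0),
        voi_params=params, seed=0,
    )
    cohort, _ = generate_cohort(spec, atlas)
    table = tiv_regression(raw_dataset(cohort))
    assert np.allclose(table["r2"], 1.0, atol=1e-12)


def test_pct_variance_invariant_to_affine_tiv_rescale(atlas):
    rng = np.random.default_rng(10)
    cohort = random_cohort(rng, n_f=10, n_m=10, n_voi=2, atlas=atlas)
    t1 = tiv_regression(raw_dataset(cohort))
    df = cohort.data.copy()
    df["tiv"] = df["tiv"] * 2.0 + 100.0
    from dataclasses import replace

    t2 = tiv_regression(raw_dataset(replace(cohort, data=df, volume_checks=False)))
    assert np.allclose(t1["pct_variance"], t2["pct_variance"], rtol=1e-10)


# --- slope/outcome association -------------------------------------------


def test_slope_outcome_perfect_antiranking():
    n = 10
    reg = pd.DataFrame({"voi": [f"v{i}" for i in range(n)], "slope": np.arange(n, dtype=float),
                        "slope_p": 0.5})
    stats = pd.DataFrame({"voi": [f"v{i}" for i in range(n)],
                          "p": np.arange(n, 0, -1, dtype=float) / 100.0,
                          "d": np.arange(n, dtype=float) / 10.0})
    out = slope_outcome_correlation(reg, stats)
    assert out.rho_slope_p == pytest.approx(-1.0)
    assert out.rho_slope_d == pytest.approx(1.0)


def test_slope_outcome_directions_on_raw_null_data(atlas):
    """The confound mechanism: steeper TIV scaling means smaller p and
    larger d for the raw group comparison.  Regions share one scale
    constant so the slope ranking reflects scaling steepness (b) rather
    than sheer region size, isolating the mechanism."""
    b = np.linspace(0.43, 1.155, 116)
    params = pd.DataFrame(
        {"voi": atlas.names, "c": 2.0 / 1545.0**b, "b": b, "sigma": 0.05, "delta": 0.0}
    )
    spec = GeneratorSpec(
        n_per_group=(171, 185), tiv_mean=(1484.5, 1606.8), tiv_sd=(77.4, 75.4),
        voi_params=params, seed=4,
    )
    cohort, _ = generate_cohort(spec, atlas)
    ds = raw_dataset(cohort)
    out = slope_outcome_correlation(tiv_regression(ds), ttest_by_voi(ds))
    assert out.rho_slope_d > 0.5
    assert out.rho_slope_p < -0.5
    assert out.rho_slope_p == pytest.approx(-out.rho_slope_d)  # p monotone in |t|


def test_slope_outcome_mismatched_regions_rejected():
    reg = pd.DataFrame({"voi": ["a", "b"], "slope": [1.0, 2.0], "slope_p": 0.5})
    stats = pd.DataFrame({"voi": ["a", "c"], "p": [0.1, 0.2], "d": [0.0, 0.1]})
    with pytest.raises(ValueError, match="different regions"):
        slope_outcome_correlation(reg, stats)


# --- slope/significance contingency --------------------------------------


def _tables_for_contingency(counts):
    """Build reg/stats tables realising a given 2x2 contingency
    {(slope_sig, diff_sig): count}."""
    rows_reg, rows_st = [], []
    i = 0
    for (ssig, dsig), k in counts.items():
        for _ in range(k):
            rows_reg.append({"voi": f"v{i}", "slope_p": 0.01 if ssig else 0.5})
            rows_st.append({"voi": f"v{i}", "p": 0.01 if dsig else 0.5})
            i += 1
    return pd.DataFrame(rows_reg), pd.DataFrame(rows_st)


def test_contingency_chi2_matches_printed_value():
    """41/11 vs 30/34 split of 116 regions gives chi2 ~ 12.35."""
    reg, st = _tables_for_contingency(
        {(True, True): 41, (True, False): 11, (False, True): 30, (False, False): 34}
    )
    out = slope_frequency_test(reg, st, alpha=0.05)
    assert out.testable
    assert out.chi2 == pytest.approx(12.35, abs=0.01)
    # hand formula: N (ad - bc)^2 / row/col products
    a, b, c, d = 41, 11, 30, 34
    hand = 116 * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    assert out.chi2 == pytest.approx(hand, rel=1e-12)


def test_contingency_degenerate_margin_flagged():
    reg, st = _tables_for_contingency({(True, True): 6})
    out = slope_frequency_test(reg, st)
    assert not out.testable
    assert out.chi2 is None and "degenerate" in out.note
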