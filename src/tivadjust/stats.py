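"""Per-region group statistics and TIV-volume regression diagnostics.

Group comparisons are pooled-variance Student t tests (two-sided), one
per region, with Cohen's d (pooled SD) and its 95% confidence interval.
The sign convention throughout is comparison minus reference: with the
default group labels, positive d means larger volumes in males.

The d confidence interval defaults to the large-sample normal
approximation, SE = sqrt((n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))), d +/-
1.96*SE; an exact noncentral-t inversion is available via
``ci_method="noncentral"``.

The regression diagnostics quantify how much of each region's variance
TIV explains (slope, R^2, slope p value) — the validation criterion for
an adjustment method is that these slopes collapse to zero after
adjustment, and that slope steepness no longer predicts which regions
show "significant" group differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.power import TTestIndPower

from .cohort import AdjustedDataset, CohortValidationError

__all__ = [
    "cohens_d",
    "d_confidence_interval",
    "d_from_t",
    "ttest_from_summary",
    "ttest_by_voi",
    "levene_test",
    "tiv_regression",
    "slope_outcome_correlation",
    "slope_frequency_test",
    "minimum_detectable_d",
]


def cohens_d(mean_cmp, mean_ref, sd_cmp, sd_ref, n_cmp, n_ref):
    """Cohen's d with pooled SD: (comparison mean - reference mean) / s_pool.

    All arguments broadcast, so vectors of per-region summaries work.
    """
    n_cmp = np.asarray(n_cmp, dtype=float)
    n_ref = np.asarray(n_ref, dtype=float)
    s_pool = np.sqrt(
        ((n_cmp - 1) * np.asarray(sd_cmp, float) ** 2 + (n_ref - 1) * np.asarray(sd_ref, float) ** 2)
        / (n_cmp + n_ref - 2)
    )
    if np.any(s_pool == 0):
        raise ZeroDivisionError("pooled SD is zero")
    return (np.asarray(mean_cmp, float) - np.asarray(mean_ref, float)) / s_pool


def d_confidence_interval(d, n1, n2, *, level: float = 0.95, method: str = "normal"):
    """Confidence interval for Cohen's d.

    ``method="normal"`` uses the large-sample SE with a z quantile.
    ``method="noncentral"`` inverts the noncentral-t distribution of
    t = d / sqrt(1/n1 + 1/n2) (scalar inputs only).
    """
    d = np.asarray(d, dtype=float)
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if method == "normal":
        se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2)))
        z = sps.norm.ppf(0.5 + level / 2.0)
        return d - z * se, d + z * se
    if method == "noncentral":
        if d.ndim > 0:
            pairs = [
                d_confidence_interval(di, n1i, n2i, level=level, method="noncentral")
                for di, n1i, n2i in zip(
                    np.atleast_1d(d),
                    np.broadcast_to(n1, d.shape).ravel(),
                    np.broadcast_to(n2, d.shape).ravel(),
                )
            ]
            lo, hi = zip(*pairs)
            return np.asarray(lo), np.asarray(hi)
        scale = np.sqrt(1.0 / n1 + 1.0 / n2)
        t_obs = float(d) / float(scale)
        df = float(n1 + n2 - 2)
        alpha = 1.0 - level
        # smallest/largest noncentrality consistent with the observed t
        lo = _nct_inverse(t_obs, df, 1.0 - alpha / 2.0)
        hi = _nct_inverse(t_obs, df, alpha / 2.0)
        return lo * float(scale), hi * float(scale)
    raise ValueError("method must be 'normal' or 'noncentral'")


def _nct_inverse(t_obs: float, df: float, prob: float) -> float:
    """Noncentrality nc such that P(T_{df,nc} > t_obs) = 1 - prob."""
    from scipy.optimize import brentq

    def f(nc):
        return sps.nct.cdf(t_obs, df, nc) - prob

    span = abs(t_obs) + 10.0
    return brentq(f, t_obs - span, t_obs + span, xtol=1e-10)


def d_from_t(t, n1, n2):
    """Cohen's d from a pooled-variance t statistic: d = t*sqrt(1/n1 + 1/n2).

    Algebraically identical to :func:`cohens_d` computed on the same data.
    """
    return np.asarray(t, float) * np.sqrt(1.0 / np.asarray(n1, float) + 1.0 / np.asarray(n2, float))


def ttest_from_summary(
    mean_cmp: float, sd_cmp: float, n_cmp: int,
    mean_ref: float, sd_ref: float, n_ref: int,
    *, alpha: float = 0.05, ci_method: str = "normal",
) -> dict:
    """Pooled two-sample t test from printed summary statistics.

    The entry point for recomputing published comparisons where only the
    group means, SDs and sizes are available.
    """
    d = float(cohens_d(mean_cmp, mean_ref, sd_cmp, sd_ref, n_cmp, n_ref))
    t = d / np.sqrt(1.0 / n_cmp + 1.0 / n_ref)
    df = n_cmp + n_ref - 2
    p = float(2.0 * sps.t.sf(abs(t), df))
    lo, hi = d_confidence_interval(d, n_cmp, n_ref, method=ci_method)
    return {
        "t": float(t), "df": df, "p": p, "d": d,
        "d_ci_low": float(lo), "d_ci_high": float(hi),
        "significant": p < alpha,
    }


def _direction_labels(d, significant, levels):
    ref, cmp_ = levels
    out = np.full(len(d), "none", dtype=object)
    out[(d > 0) & significant] = f"{cmp_}>{ref}"
    out[(d < 0) & significant] = f"{ref}>{cmp_}"
    return out


def ttest_by_voi(
    dataset: AdjustedDataset,
    *,
    alpha: float = 0.05,
    marginal_alpha: float = 0.1,
    ci_method: str = "normal",
) -> pd.DataFrame:
    """Independent-groups Student t test per region.

    Returns one row per region: group means/SDs/sizes, t, df, two-sided
    p, Cohen's d with CI, a direction label, and significance flags at
    ``alpha`` plus a ``marginal`` flag at ``marginal_alpha`` (mirroring
    reduced-power subsample reporting).
    """
    cohort = dataset.table
    cohort.require_two_groups()
    ref, cmp_ = cohort.group_levels
    mask = cohort.comparison_mask()
    volumes = cohort.voi_matrix()
    x_cmp, x_ref = volumes[mask], volumes[~mask]
    n_cmp, n_ref = len(x_cmp), len(x_ref)

    res = sps.ttest_ind(x_cmp, x_ref, axis=0, equal_var=True)
    mean_cmp, mean_ref = x_cmp.mean(axis=0), x_ref.mean(axis=0)
    sd_cmp = x_cmp.std(axis=0, ddof=1)
    sd_ref = x_ref.std(axis=0, ddof=1)
    d = cohens_d(mean_cmp, mean_ref, sd_cmp, sd_ref, n_cmp, n_ref)
    lo, hi = d_confidence_interval(d, n_cmp, n_ref, method=ci_method)
    significant = res.pvalue < alpha

    return pd.DataFrame(
        {
            "voi": cohort.voi_names,
            f"mean_{ref}": mean_ref,
            f"sd_{ref}": sd_ref,
            f"n_{ref}": n_ref,
            f"mean_{cmp_}": mean_cmp,
            f"sd_{cmp_}": sd_cmp,
            f"n_{cmp_}": n_cmp,
            "t": res.statistic,
            "df": n_cmp + n_ref - 2,
            "p": res.pvalue,
            "d": d,
            "d_ci_low": lo,
            "d_ci_high": hi,
            "direction": _direction_labels(d, significant, cohort.group_levels),
            "significant": significant,
            "marginal": (res.pvalue < marginal_alpha) & ~significant,
        }
    )


def levene_test(values, groups) -> tuple[float, float]:
    """Levene's homogeneity-of-variance test with mean centering."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if any(len(s) < 2 for s in samples) or len(samples) < 2:
        raise CohortValidationError("Levene's test needs >= 2 values in each of 2 groups")
    stat, p = sps.levene(*samples, center="mean")
    return float(stat), float(p)


def tiv_regression(dataset: AdjustedDataset) -> pd.DataFrame:
    """OLS of each (adjusted) region volume on TIV.

    Per region: slope (ml per ml of TIV for ml-scale datasets), intercept,
    R^2, two-sided slope p value, and percent of variance explained
    (100 * R^2).
    """
    cohort = dataset.table
    tiv = cohort.tiv
    if np.ptp(tiv) == 0:
        from .adjust import DegenerateDesignError

        raise DegenerateDesignError("TIV is constant across the sample")
    y = cohort.voi_matrix()
    n = len(tiv)
    xc = tiv - tiv.mean()
    sxx = xc @ xc
    slope = xc @ (y - y.mean(axis=0)) / sxx
    intercept = y.mean(axis=0) - slope * tiv.mean()
    resid = y - (intercept[None, :] + slope[None, :] * tiv[:, None])
    ss_res = (resid**2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        se_slope = np.sqrt(ss_res / (n - 2) / sxx)
        tval = np.where(se_slope > 0, slope / se_slope, 0.0)
    slope_p = 2.0 * sps.t.sf(np.abs(tval), n - 2)
    return pd.DataFrame(
        {
            "voi": cohort.voi_names,
            "slope": slope,
            "intercept": intercept,
            "r2": r2,
            "slope_p": slope_p,
            "pct_variance": 100.0 * r2,
        }
    )


@dataclass
class SlopeOutcomeCorrelation:
    """Rank correlations of TIV-volume slopes with group-test outcomes."""

    rho_slope_p: float
    p_slope_p: float
    rho_slope_d: float
    p_slope_d: float


def slope_outcome_correlation(
    regressions: pd.DataFrame, stats_table: pd.DataFrame
) -> SlopeOutcomeCorrelation:
    """Spearman correlations of per-region slopes with p values and d values.

    In raw data the slope of the TIV-volume line predicts both how likely
    and how large a group difference is (negative rho with p, positive
    with d); after a valid adjustment both correlations vanish.
    """
    merged = regressions[["voi", "slope"]].merge(
        stats_table[["voi", "p", "d"]], on="voi", how="inner", validate="one_to_one"
    )
    if len(merged) != len(regressions) or len(merged) != len(stats_table):
        raise ValueError("regression and stats tables cover different regions")
    rho_p, p_p = sps.spearmanr(merged["slope"], merged["p"])
    rho_d, p_d = sps.spearmanr(merged["slope"], merged["d"])
    return SlopeOutcomeCorrelation(float(rho_p), float(p_p), float(rho_d), float(p_d))


@dataclass
class SlopeFrequencyTest:
    """2x2 association between slope significance and group-test significance."""

    table: pd.DataFrame
    chi2: float | None
    p: float | None
    testable: bool
    note: str = ""


def slope_frequency_test(
    regressions: pd.DataFrame,
    stats_table: pd.DataFrame,
    *,
    alpha: float = 0.05,
) -> SlopeFrequencyTest:
    """Chi-squared test (no continuity correction) of the 2x2 contingency
    slope-significant x group-difference-significant across regions.

    Degenerate margins (a row or column of zeros) are reported as
    untestable rather than raising.
    """
    merged = regressions[["voi", "slope_p"]].merge(
        stats_table[["voi", "p"]], on="voi", how="inner", validate="one_to_one"
    )
    slope_sig = merged["slope_p"] < alpha
    diff_sig = merged["p"] < alpha
    table = pd.crosstab(slope_sig, diff_sig).reindex(
        index=[True, False], columns=[True, False], fill_value=0
    )
    table.index.name = "slope_significant"
    table.columns.name = "difference_significant"
    arr = table.to_numpy()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return SlopeFrequencyTest(table, None, None, False, "degenerate margin")
    chi2, p, _, _ = sps.chi2_contingency(arr, correction=False)
    return SlopeFrequencyTest(table, float(chi2), float(p), True)


def minimum_detectable_d(
    n1: int, n2: int, *, power: float = 0.8, alpha: float = 0.05
) -> float:
    """Sensitivity power analysis for a two-sided two-sample t test.

    Smallest standardised difference detectable with the given power at
    the given alpha for group sizes ``n1`` and ``n2``.
    """
    solver = TTestIndPower()
    d = solver.solve_power(
        effect_size=None, nobs1=n1, ratio=n2 / n1, alpha=alpha, power=power,
        alternative="two-sided",
    )
    return float(d)
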