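"""Head-size (TIV) adjustment of regional volumes.

Four procedures for removing total-intracranial-volume scaling effects
from per-region volumes before group comparison:

proportion
    ``VOI_adj = VOI / TIV``.  Parameter-free; implicitly assumes strict
    proportionality (allometric exponent b = 1).  When the true exponent
    is below 1 this over-corrects and *inverts* the TIV-volume
    relationship rather than removing it.
power-corrected proportion (PCP)
    ``VOI_adj = VOI / TIV**b`` with b the slope of the ordinary
    least-squares regression of log(VOI) on log(TIV).
residuals
    ``VOI_adj = VOI - b * (TIV - mean(TIV))`` with b the slope of the
    linear VOI-on-TIV regression.  Adjusted values keep the ml scale and
    the original per-region mean, and are exactly uncorrelated with TIV
    in-sample (OLS orthogonality).
covariate regression
    ``VOI = b0 + b_tiv * TIV + b_sex * sex + error`` fitted per region
    with sex coded 0 = reference (F) / 1 = comparison (M).  This method
    produces no adjusted volumes; the sex coefficient, its p value, and
    the derived effect size ``d = b_sex / SD(VOI)`` are the group test.

Every fit pools both groups (there is no control group in a sex
comparison), and all fits are exact closed-form least squares.  The
natural logarithm is used for the PCP fit; the slope is invariant to the
base.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import AdjustedDataset, CohortTable, CohortValidationError

__all__ = [
    "adjust_proportion",
    "fit_pcp",
    "adjust_pcp",
    "adjust_residuals",
    "fit_covariate_regression",
]


class DegenerateDesignError(ValueError):
    """Raised when a regression design is rank-deficient (e.g. constant TIV)."""


def _check_tiv_varies(tiv: np.ndarray) -> None:
    if np.ptp(tiv) == 0:
        raise DegenerateDesignError("TIV is constant across the sample")


def adjust_proportion(cohort: CohortTable) -> AdjustedDataset:
    """Divide every volume by the subject's TIV.

    The result is a dimensionless ratio table; no parameters are fitted.
    """
    ratios = cohort.voi_matrix() / cohort.tiv[:, None]
    table = cohort.with_volumes(ratios, provenance=f"{cohort.provenance}|proportion")
    return AdjustedDataset(table=table, method="proportion")


def fit_pcp(cohort: CohortTable) -> pd.DataFrame:
    """Per-region power-law fit: OLS of log(VOI) on log(TIV), whole sample.

    Returns a frame with columns ``voi``, ``b`` (exponent = slope) and
    ``intercept`` (natural-log units).  Zero volumes have no logarithm;
    they raise, with the advice to exclude the offending region.
    """
    volumes = cohort.voi_matrix()
    if np.any(volumes <= 0):
        bad = [v for v, any0 in zip(cohort.voi_names, (volumes <= 0).any(axis=0)) if any0]
        raise ValueError(
            f"zero volume(s) in {bad[:5]}: the power-law fit needs strictly "
            "positive volumes; exclude these regions first"
        )
    _check_tiv_varies(cohort.tiv)
    x = np.log(cohort.tiv)
    y = np.log(volumes)
    xc = x - x.mean()
    b = xc @ (y - y.mean(axis=0)) / (xc @ xc)
    intercept = y.mean(axis=0) - b * x.mean()
    return pd.DataFrame({"voi": cohort.voi_names, "b": b, "intercept": intercept})


def adjust_pcp(cohort: CohortTable, fits: pd.DataFrame | None = None) -> AdjustedDataset:
    """Power-corrected proportion: ``VOI / TIV**b`` per subject and region.

    ``fits`` defaults to :func:`fit_pcp` on the same cohort; pass a
    pre-computed table to adjust a subsample with exponents estimated
    elsewhere.
    """
    if fits is None:
        fits = fit_pcp(cohort)
    fit_idx = fits.set_index("voi")
    missing = [v for v in cohort.voi_names if v not in fit_idx.index]
    if missing:
        raise KeyError(f"no power-law fit for region(s) {missing[:5]}")
    b = fit_idx.loc[cohort.voi_names, "b"].to_numpy(dtype=float)
    adjusted = cohort.voi_matrix() / cohort.tiv[:, None] ** b[None, :]
    table = cohort.with_volumes(adjusted, provenance=f"{cohort.provenance}|pcp")
    return AdjustedDataset(table=table, method="pcp", fit_params=fits.reset_index(drop=True))


def adjust_residuals(cohort: CohortTable) -> AdjustedDataset:
    """Residuals method: remove the fitted linear TIV effect, keep the mean.

    The per-region slope and the grand TIV mean are estimated on the whole
    sample.  Adjusted volumes stay in ml; their sample covariance with TIV
    is exactly zero, and their mean equals the raw mean.
    """
    tiv = cohort.tiv
    _check_tiv_varies(tiv)
    volumes = cohort.voi_matrix()
    tiv_mean = tiv.mean()
    xc = tiv - tiv_mean
    b = xc @ (volumes - volumes.mean(axis=0)) / (xc @ xc)
    adjusted = volumes - b[None, :] * xc[:, None]
    fits = pd.DataFrame({"voi": cohort.voi_names, "b": b, "tiv_mean": tiv_mean})
    table = cohort.with_volumes(adjusted, provenance=f"{cohort.provenance}|residuals")
    return AdjustedDataset(table=table, method="residuals", fit_params=fits)


def fit_covariate_regression(
    cohort: CohortTable, *, d_sd: str = "whole_sample"
) -> pd.DataFrame:
    """Two-predictor OLS of each region on TIV and group, whole sample.

    Group (sex) is coded 0 for the reference level and 1 for the
    comparison level, so a positive ``b_sex`` means comparison > reference
    (M > F under the default labels).  Returns one row per region with
    unstandardised coefficients (``b0``, ``b_tiv``, ``b_sex``),
    standardised coefficients (``beta_tiv``, ``beta_sex``), semi-partial
    correlations (``sr_tiv``, ``sr_sex``), coefficient p values and
    ``d_sex = b_sex / SD(VOI)``.

    ``d_sd`` selects the SD used for ``d_sex``: ``"whole_sample"``
    (default) or ``"pooled"`` (pooled within-group SD).
    """
    cohort.require_two_groups()
    tiv = cohort.tiv
    _check_tiv_varies(tiv)
    n = cohort.n
    if n <= 3:
        raise CohortValidationError("covariate regression needs n > 3")
    sex = cohort.comparison_mask().astype(float)
    volumes = cohort.voi_matrix()

    X = np.column_stack([np.ones(n), tiv, sex])
    if np.linalg.matrix_rank(X) < 3:
        raise DegenerateDesignError("rank-deficient design (TIV collinear with group?)")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ volumes  # 3 x n_voi
    resid = volumes - X @ beta
    df_resid = n - 3
    sigma2 = (resid**2).sum(axis=0) / df_resid
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    tvals = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tvals), df_resid)

    sd_y = volumes.std(axis=0, ddof=1)
    sd_tiv = tiv.std(ddof=1)
    sd_sex = sex.std(ddof=1)
    beta_tiv = beta[1] * sd_tiv / sd_y
    beta_sex = beta[2] * sd_sex / sd_y

    # semi-partial correlation from the coefficient t and the model R^2:
    # sr^2 = t^2 (1 - R^2) / df_resid
    ss_tot = ((volumes - volumes.mean(axis=0)) ** 2).sum(axis=0)
    r2 = 1.0 - (resid**2).sum(axis=0) / ss_tot
    sr_tiv = np.sign(beta[1]) * np.sqrt(tvals[1] ** 2 * (1.0 - r2) / df_resid)
    sr_sex = np.sign(beta[2]) * np.sqrt(tvals[2] ** 2 * (1.0 - r2) / df_resid)

    if d_sd == "whole_sample":
        d_denom = sd_y
    elif d_sd == "pooled":
        m = sex.astype(bool)
        v_ref = volumes[~m].var(axis=0, ddof=1)
        v_cmp = volumes[m].var(axis=0, ddof=1)
        n_ref, n_cmp = int((~m).sum()), int(m.sum())
        d_denom = np.sqrt(((n_ref - 1) * v_ref + (n_cmp - 1) * v_cmp) / (n_ref + n_cmp - 2))
    else:
        raise ValueError("d_sd must be 'whole_sample' or 'pooled'")

    return pd.DataFrame(
        {
            "voi": cohort.voi_names,
            "b0": beta[0],
            "b_tiv": beta[1],
            "b_sex": beta[2],
            "beta_tiv": beta_tiv,
            "beta_sex": beta_sex,
            "sr_tiv": sr_tiv,
            "sr_sex": sr_sex,
            "p_tiv": pvals[1],
            "p_sex": pvals[2],
            "d_sex": beta[2] / d_denom,
            "r2": r2,
            "df": df_resid,
        }
    )
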