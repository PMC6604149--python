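"""Agreement among adjustment methods and against a criterion dataset.

Each method's per-region outcome is reduced to a trinary code: +1 for a
significant comparison>reference difference (M > F), 0 for no significant
difference, -1 for a significant reference>comparison difference.  On top
of these codes the module computes:

* Randolph's free-marginal multi-rater kappa (nominal significant /
  not-significant agreement across all methods, bootstrap CI),
* Kendall's W over the methods' p-value rankings (midrank tie correction),
* the pairwise Spearman matrix of p-value orderings,
* unweighted Cohen's kappa of a candidate's trinary codes against a
  criterion (the TIV-matched benchmark), with a Landis-Koch agreement
  band and the hit / false-positive / false-negative / reversion
  taxonomy of the disagreements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "code_differences",
    "free_marginal_kappa",
    "percent_overall_agreement",
    "kendall_w",
    "spearman_matrix",
    "criterion_agreement",
    "landis_koch_band",
    "CriterionAgreement",
]

VALID_CODES = (-1, 0, 1)


def code_differences(stats_table: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Trinary significance codes from a per-region stats table.

    Requires ``voi``, ``p`` and ``d`` columns (a t-test table or a
    covariate-regression table renamed accordingly).  Returns a Series
    indexed by region with values in {-1, 0, +1}.
    """
    sig = stats_table["p"].to_numpy() < alpha
    d = stats_table["d"].to_numpy()
    codes = np.where(sig, np.sign(d).astype(int), 0)
    return pd.Series(codes, index=stats_table["voi"].to_numpy(), name="code", dtype=int)


def _align_codes(codes: pd.DataFrame | dict) -> pd.DataFrame:
    df = pd.DataFrame(codes)
    if df.isna().any().any():
        raise ValueError("code vectors cover different regions")
    bad = ~df.isin(VALID_CODES)
    if bad.any().any():
        raise ValueError("codes must be -1, 0 or +1")
    return df.astype(int)


def _mean_pairwise_agreement(binary: np.ndarray) -> float:
    """Mean over items of the proportion of agreeing rater pairs."""
    n, m = binary.shape
    agree = np.zeros(n)
    n_pairs = m * (m - 1) / 2
    for a in range(m):
        for b in range(a + 1, m):
            agree += binary[:, a] == binary[:, b]
    return float(np.mean(agree / n_pairs))


def free_marginal_kappa(
    codes: pd.DataFrame | dict,
    *,
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Randolph's free-marginal multi-rater kappa over binarised codes.

    Codes are binarised to significant / not-significant (the agreement is
    nominal), so with k = 2 categories kappa = (Po - 1/2) / (1 - 1/2)
    where Po is the mean pairwise proportion of agreement across regions.
    The CI is a percentile bootstrap over regions (case resampling),
    seed-controlled.
    """
    df = _align_codes(codes)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 methods (raters)")
    binary = (df.to_numpy() != 0).astype(int)

    def kappa_of(rows: np.ndarray) -> float:
        po = _mean_pairwise_agreement(binary[rows])
        return (po - 0.5) / 0.5

    n = binary.shape[0]
    kappa = kappa_of(np.arange(n))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = kappa_of(rng.integers(n, size=n))
    lo, hi = np.quantile(boots, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    return float(kappa), (float(lo), float(hi))


def percent_overall_agreement(codes: pd.DataFrame | dict) -> float:
    """Mean pairwise percent agreement of binarised codes across regions."""
    df = _align_codes(codes)
    binary = (df.to_numpy() != 0).astype(int)
    return 100.0 * _mean_pairwise_agreement(binary)


def kendall_w(p_table: pd.DataFrame) -> float:
    """Kendall's coefficient of concordance over p-value rankings.

    ``p_table`` has one column per method, one row per region; p values
    are the ranked quantity (they are comparable across methods, unlike
    raw statistics).  Midrank ties enter through the standard tie
    correction: W = 12 S / (m^2 (n^3 - n) - m * sum_j T_j) with
    T_j = sum over tie groups of (t^3 - t).
    """
    if p_table.shape[1] < 2:
        raise ValueError("need at least 2 methods")
    if p_table.isna().any().any():
        raise ValueError("p tables cover different regions")
    n, m = p_table.shape
    ranks = p_table.rank(axis=0, method="average").to_numpy()
    totals = ranks.sum(axis=1)
    s = float(((totals - totals.mean()) ** 2).sum())
    tie_term = 0.0
    for j in range(m):
        _, counts = np.unique(ranks[:, j], return_counts=True)
        tie_term += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * tie_term
    if denom <= 0:
        return 1.0  # all raters fully tied: rankings trivially concordant
    return 12.0 * s / denom


def spearman_matrix(p_table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rho (and p values) of the methods' p orderings."""
    if p_table.isna().any().any():
        raise ValueError("p tables cover different regions")
    methods = list(p_table.columns)
    k = len(methods)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            r, p = sps.spearmanr(p_table.iloc[:, a], p_table.iloc[:, b])
            rho[a, b] = rho[b, a] = r
            pmat[a, b] = pmat[b, a] = p
    return (
        pd.DataFrame(rho, index=methods, columns=methods),
        pd.DataFrame(pmat, index=methods, columns=methods),
    )


LANDIS_KOCH_BANDS = (
    (0.00, "slight"),
    (0.21, "fair"),
    (0.41, "moderate"),
    (0.61, "substantial"),
    (0.81, "almost perfect"),
)


def landis_koch_band(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value ("poor" below 0)."""
    if kappa < 0.0:
        return "poor"
    label = "slight"
    for lower, name in LANDIS_KOCH_BANDS:
        if kappa >= lower:
            label = name
    return label


@dataclass
class CriterionAgreement:
    """Cohen's kappa of candidate vs criterion codes, plus the taxonomy."""

    kappa: float
    ci: tuple[float, float]
    band: str
    taxonomy: dict[str, int]
    confusion: pd.DataFrame

    @property
    def n(self) -> int:
        return int(sum(self.taxonomy.values()))


def criterion_agreement(
    candidate: pd.Series, criterion: pd.Series, *, ci_level: float = 0.95
) -> CriterionAgreement:
    """Compare a method's trinary codes with the criterion's.

    Computes unweighted Cohen's kappa on the {-1, 0, +1} codes (CI from
    the large-sample standard error), the Landis-Koch band, and the
    outcome taxonomy: ``hits_sig`` (significant, same sign in both),
    ``hits_null`` (significant in neither), ``false_pos`` (candidate
    significant, criterion not), ``false_neg`` (criterion significant,
    candidate not) and ``reversions`` (significant with opposite signs).
    The five counts partition the region set.
    """
    df = _align_codes({"candidate": candidate, "criterion": criterion})
    cand = df["candidate"].to_numpy()
    crit = df["criterion"].to_numpy()
    n = len(df)

    confusion = pd.crosstab(
        pd.Categorical(cand, categories=VALID_CODES),
        pd.Categorical(crit, categories=VALID_CODES),
        dropna=False,
    )
    confusion.index.name = "candidate"
    confusion.columns.name = "criterion"
    arr = confusion.to_numpy()
    po = float(np.trace(arr)) / n
    pe = float((arr.sum(axis=1) / n) @ (arr.sum(axis=0) / n))
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
        se = 0.0
    else:
        kappa = (po - pe) / (1.0 - pe)
        se = np.sqrt(po * (1.0 - po) / (n * (1.0 - pe) ** 2))
    z = sps.norm.ppf(0.5 + ci_level / 2.0)
    ci = (float(kappa - z * se), float(kappa + z * se))

    taxonomy = {
        "hits_sig": int(np.sum((cand != 0) & (cand == crit))),
        "hits_null": int(np.sum((cand == 0) & (crit == 0))),
        "false_pos": int(np.sum((cand != 0) & (crit == 0))),
        "false_neg": int(np.sum((cand == 0) & (crit != 0))),
        "reversions": int(np.sum((cand != 0) & (crit != 0) & (cand != crit))),
    }
    assert sum(taxonomy.values()) == n
    return CriterionAgreement(
        kappa=float(kappa), ci=ci, band=landis_koch_band(float(kappa)),
        taxonomy=taxonomy, confusion=confusion,
    )
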