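"""Replication scoring, intuitive effect-size indexes, multiplicity control.

Replication score
    For each region the trinary codes of several TIV-free datasets
    (+1 significant M>F, -1 significant F>M, 0 neither) are summed; the
    magnitude of the sum is interpreted without its sign.  A difference is
    "replicable" when observed, with one direction, in all or all but one
    of the datasets (|score| >= n_datasets - 1); a score of exactly 0 is
    the strict criterion for consistent absence ("sameness").

Effect-size conversions
    For two unit-variance normal populations separated by d: the percent
    of overlap (overlapping coefficient) is 200 * Phi(-|d|/2), and the
    percent of superiority (common-language effect size) — the chance a
    random member of the comparison population exceeds a random member of
    the reference population — is 100 * Phi(d / sqrt(2)).

Multiple-comparison corrections
    Benjamini-Krieger-Yekutieli two-stage adaptive FDR (stage-one BH at
    alpha/(1+alpha), re-run with the estimated number of true nulls),
    Benjamini-Hochberg step-up, Holm step-down, and single-step
    Bonferroni-Dunn; all delegated to statsmodels' multipletests.  For
    any p vector the rejection sets nest: Bonferroni ⊆ Holm ⊆ BH.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "overlap_from_d",
    "superiority_from_d",
    "replication_scores",
    "mc_correct",
    "correction_profile",
    "CORRECTIONS",
]

#: Supported corrections, in decreasing order of expected statistical power.
CORRECTIONS = ("bky", "bh", "holm", "bonferroni")

_STATSMODELS_METHOD = {
    "bky": "fdr_tsbky",
    "bh": "fdr_bh",
    "holm": "holm",
    "bonferroni": "bonferroni",
}


def overlap_from_d(d) -> np.ndarray | float:
    """Percent of overlap of two unit-variance normals separated by d.

    100% at d = 0, strictly decreasing in |d|.
    """
    d = np.asarray(d, dtype=float)
    out = 200.0 * sps.norm.cdf(-np.abs(d) / 2.0)
    return float(out) if out.ndim == 0 else out


def superiority_from_d(d) -> np.ndarray | float:
    """Percent of superiority (common-language effect size), 100*Phi(d/sqrt 2).

    50% at d = 0; superiority(-d) = 100 - superiority(d).
    """
    d = np.asarray(d, dtype=float)
    out = 100.0 * sps.norm.cdf(d / np.sqrt(2.0))
    return float(out) if out.ndim == 0 else out


def replication_scores(
    codes: pd.DataFrame, d_values: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Score cross-dataset replication of per-region differences.

    ``codes`` has one row per region, one column per dataset, entries in
    {-1, 0, +1}.  ``d_values``, if given, has the same shape and carries
    each dataset's Cohen's d; the per-region mean (over all datasets,
    significant or not) feeds the overlap/superiority conversions.

    Returns a frame indexed like ``codes`` with columns ``score``,
    ``replicable``, ``sameness`` and, when d values are supplied,
    ``mean_d``, ``overlap_pct``, ``superiority_pct``.  Scoring is
    invariant to dataset (column) order.
    """
    if codes.shape[1] < 3:
        raise ValueError("replication scoring needs at least 3 datasets")
    if codes.isna().any().any():
        raise ValueError("datasets cover different regions")
    arr = codes.to_numpy()
    if not np.isin(arr, (-1, 0, 1)).all():
        raise ValueError("codes must be -1, 0 or +1")
    m = codes.shape[1]
    score = arr.sum(axis=1)
    out = pd.DataFrame(
        {
            "score": score,
            "replicable": np.abs(score) >= m - 1,
            "sameness": score == 0,
        },
        index=codes.index,
    )
    if d_values is not None:
        if list(d_values.index) != list(codes.index):
            raise ValueError("d_values index must match codes index")
        mean_d = d_values.mean(axis=1)
        out["mean_d"] = mean_d
        out["overlap_pct"] = overlap_from_d(mean_d.to_numpy())
        out["superiority_pct"] = superiority_from_d(mean_d.to_numpy())
    return out


def mc_correct(
    p_values, method: str, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one multiple-comparison procedure to a p-value vector.

    Returns ``(rejected, p_adjusted)``.  ``method`` is one of ``bky``,
    ``bh``, ``holm``, ``bonferroni``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("p_values must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if method not in _STATSMODELS_METHOD:
        raise ValueError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method=_STATSMODELS_METHOD[method])
    return reject, np.minimum(p_adj, 1.0)


def correction_profile(
    p_by_dataset: dict[str, pd.Series] | pd.DataFrame,
    *,
    corrections=CORRECTIONS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count significant regions per dataset under each correction.

    Rows are datasets, columns ``uncorrected`` plus each requested
    correction; entries are counts of rejected regions at ``alpha``.
    """
    if isinstance(p_by_dataset, pd.DataFrame):
        p_by_dataset = {c: p_by_dataset[c] for c in p_by_dataset.columns}
    rows = {}
    for name, p in p_by_dataset.items():
        p = np.asarray(p, dtype=float)
        row = {"uncorrected": int(np.sum(p < alpha))}
        for corr in corrections:
            rejected, _ = mc_correct(p, corr, alpha=alpha)
            row[corr] = int(rejected.sum())
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")[["uncorrected", *corrections]]
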