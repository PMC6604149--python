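"""Criterial subsamples: TIV matching and calibrated single-group splits.

Two benchmark constructions used to separate head-size effects from
genuine group effects:

* a **TIV-matched subsample** pairs each subject with the closest-TIV
  subject of the other group, admitting a pair only when the TIV gap is
  within a caliper (10 ml by default).  Comparing matched groups is the
  one undisputed way to remove head-size variation entirely, so the
  matched comparison serves as the ground-truth estimate of the group
  effect.
* **calibrated single-group splits** take one group only (e.g. only the
  males), median-split it by TIV into a small-TIV and a large-TIV pool,
  and search for two equally sized subgroups whose TIV difference hits a
  target standardised d (1.6 by default — the female-male TIV gap).
  Comparing the resulting large/small groups estimates what head size
  alone does, with the grouping variable removed by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .cohort import CohortTable

__all__ = ["MatchResult", "CalibratedSplit", "tiv_match", "calibrate_split"]


@dataclass
class MatchResult:
    """Outcome of cross-group TIV matching."""

    pairs: list[tuple[str, str, float]]  # (reference id, comparison id, |TIV diff| ml)
    matched_cohort: CohortTable
    unmatched: list[str]
    caliper: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def tiv_match(
    cohort: CohortTable, caliper: float = 10.0, *, method: str = "greedy"
) -> MatchResult:
    """Pair subjects across groups by nearest TIV within a caliper.

    ``method="greedy"`` (default) repeatedly accepts the unmatched
    cross-group pair with the smallest TIV difference until no admissible
    pair remains; ties break on subject-id order, so the result is
    deterministic and invariant to input row order.  ``method="optimal"``
    solves the assignment problem exactly (maximum number of admissible
    pairs, then minimum total TIV difference); greedy approximates it and
    can differ in rare near-tie configurations.

    An empty pairing is a valid result, not an error.
    """
    if method not in {"greedy", "optimal"}:
        raise ValueError("method must be 'greedy' or 'optimal'")
    cohort.require_two_groups(min_per_group=1)
    ref, cmp_ = cohort.group_levels
    df = cohort.data
    ref_rows = df[df["group"] == ref].sort_values("subject_id")
    cmp_rows = df[df["group"] == cmp_].sort_values("subject_id")
    ref_ids = ref_rows["subject_id"].to_list()
    cmp_ids = cmp_rows["subject_id"].to_list()
    ref_tiv = ref_rows["tiv"].to_numpy(dtype=float)
    cmp_tiv = cmp_rows["tiv"].to_numpy(dtype=float)

    diffs = np.abs(ref_tiv[:, None] - cmp_tiv[None, :])

    if method == "greedy":
        pairs_idx = _greedy_pairs(diffs, caliper)
    else:
        pairs_idx = _optimal_pairs(diffs, caliper)

    pairs = [(ref_ids[i], cmp_ids[j], float(diffs[i, j])) for i, j in pairs_idx]
    paired_ids = [sid for p in pairs for sid in p[:2]]
    unmatched = sorted(set(ref_ids + cmp_ids) - set(paired_ids))
    matched = cohort.subset(paired_ids, provenance=f"{cohort.provenance}|tiv_matched")
    return MatchResult(pairs=pairs, matched_cohort=matched, unmatched=unmatched, caliper=caliper)


def _greedy_pairs(diffs: np.ndarray, caliper: float) -> list[tuple[int, int]]:
    admissible = np.argwhere(diffs <= caliper)
    order = sorted(
        (float(diffs[i, j]), int(i), int(j)) for i, j in admissible
    )  # ties break on (reference index, comparison index), i.e. id order
    used_i: set[int] = set()
    used_j: set[int] = set()
    out: list[tuple[int, int]] = []
    for _, i, j in order:
        if i in used_i or j in used_j:
            continue
        out.append((i, j))
        used_i.add(i)
        used_j.add(j)
    return out


def _optimal_pairs(diffs: np.ndarray, caliper: float) -> list[tuple[int, int]]:
    # Big-M on inadmissible cells: the assignment then prefers every
    # admissible pair over any inadmissible one (max cardinality), and
    # minimises total difference among admissible pairings.
    big = caliper * (diffs.size + 1.0) + float(diffs.max(initial=0.0)) + 1.0
    cost = np.where(diffs <= caliper, diffs, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if diffs[i, j] <= caliper]


@dataclass
class CalibratedSplit:
    """Outcome of the large/small-TIV calibration search on one group."""

    large_group: list[str]
    small_group: list[str]
    achieved_d: float
    iterations: int
    seed: int
    converged: bool
    target_d: float
    tolerance: float
    trace: list[float] = field(default_factory=list, repr=False)

    def to_cohort(self, cohort: CohortTable) -> CohortTable:
        """Build a two-group cohort ("S" reference vs "L" comparison)."""
        from dataclasses import replace

        sub = cohort.subset(self.small_group + self.large_group)
        df = sub.data.copy()
        df["group"] = ["S"] * len(self.small_group) + ["L"] * len(self.large_group)
        return replace(
            sub, data=df, group_levels=("S", "L"),
            provenance=f"{cohort.provenance}|calibrated_split",
        )


def _split_d(large: np.ndarray, small: np.ndarray) -> float:
    n1, n2 = len(large), len(small)
    sp = np.sqrt(
        ((n1 - 1) * large.var(ddof=1) + (n2 - 1) * small.var(ddof=1)) / (n1 + n2 - 2)
    )
    gap = float(large.mean() - small.mean())
    if sp == 0.0:  # degenerate all-equal groups: 0 if means match, else unbounded
        return 0.0 if gap == 0.0 else float(np.sign(gap)) * float("inf")
    return gap / float(sp)


def calibrate_split(
    cohort: CohortTable,
    group_size: int,
    *,
    target_d: float = 1.6,
    tolerance: float = 0.06,
    max_iter: int = 10_000,
    seed: int = 0,
) -> CalibratedSplit:
    """Search for large/small-TIV subgroups with a target standardised gap.

    The single-group cohort is sorted by TIV and median-split into two
    frozen pools; ``group_size`` subjects are drawn from each, then a
    stochastic local search iterates two move types — replacing a selected
    member with an unselected member of its own pool, or permuting one
    member between the two selected groups — accepting any move that
    brings the achieved pooled-SD Cohen's d closer to ``target_d``.  The
    search stops when |achieved - target| <= ``tolerance`` or after
    ``max_iter`` proposals; non-convergence is reported, not raised.
    """
    levels_present = cohort.data["group"].unique()
    if len(levels_present) != 1:
        raise ValueError("calibrate_split expects a single-group cohort")
    n = cohort.n
    if 2 * group_size > n:
        raise ValueError(f"cannot draw 2x{group_size} subjects from {n}")

    rng = np.random.default_rng(seed)
    df = cohort.data.sort_values(["tiv", "subject_id"]).reset_index(drop=True)
    half = n // 2
    if group_size > min(half, n - half):
        raise ValueError("group_size exceeds a median-split pool")

    # frozen pools; groups and the unselected remainder of each pool are
    # id/tiv arrays that the move set mutates.
    ids = df["subject_id"].to_numpy()
    tiv = df["tiv"].to_numpy(dtype=float)
    pool = {"small": np.arange(half), "large": np.arange(half, n)}
    group: dict[str, np.ndarray] = {}
    spare: dict[str, np.ndarray] = {}
    for side in ("small", "large"):
        pick = rng.choice(len(pool[side]), size=group_size, replace=False)
        mask = np.zeros(len(pool[side]), dtype=bool)
        mask[pick] = True
        group[side] = pool[side][mask]
        spare[side] = pool[side][~mask]

    def achieved() -> float:
        return _split_d(tiv[group["large"]], tiv[group["small"]])

    current = achieved()
    trace = [current]
    iterations = 0
    while abs(current - target_d) > tolerance and iterations < max_iter:
        iterations += 1
        g = {s: a.copy() for s, a in group.items()}
        sp = {s: a.copy() for s, a in spare.items()}
        if rng.random() < 0.5:
            # within-pool replacement: a group member returns to its
            # pool's unselected remainder and is replaced from it
            side = "small" if rng.random() < 0.5 else "large"
            if len(sp[side]) == 0:
                continue
            k = int(rng.integers(len(g[side])))
            m = int(rng.integers(len(sp[side])))
            g[side][k], sp[side][m] = sp[side][m], g[side][k]
        else:
            # between-pool permutation: exchange one member between the
            # two selected groups
            k_s = int(rng.integers(len(g["small"])))
            k_l = int(rng.integers(len(g["large"])))
            g["small"][k_s], g["large"][k_l] = g["large"][k_l], g["small"][k_s]
        new_d = _split_d(tiv[g["large"]], tiv[g["small"]])
        if abs(new_d - target_d) < abs(current - target_d):
            group, spare = g, sp
            current = new_d
            trace.append(current)

    return CalibratedSplit(
        large_group=sorted(ids[group["large"]].tolist()),
        small_group=sorted(ids[group["small"]].tolist()),
        achieved_d=current,
        iterations=iterations,
        seed=seed,
        converged=abs(current - target_d) <= tolerance,
        target_d=target_d,
        tolerance=tolerance,
        trace=trace,
    )
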