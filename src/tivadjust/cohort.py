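"""Cohort data model and delimited-text I/O.

A cohort is a per-subject table with a subject identifier, a two-level
group label (by default sex, with "F" as the reference level and "M" as
the comparison level), total intracranial volume (TIV, ml), one column
per atlas region (VOI volumes, ml), and optional scalar covariates such
as age or education.  Every analysis stage in the package consumes and
produces this structure.

Volumes are stored in ml.  Tables whose volumes are evidently in mm^3
(median TIV above 100 000) are rescaled on read, with a logged warning;
CAT12-style pipelines emit mm^3 while the analyses here are reported
in ml.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RegionAtlas, default_atlas

__all__ = [
    "CohortTable",
    "AdjustedDataset",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
]

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = ("subject_id", "group", "tiv")

#: Median-TIV threshold above which volumes are taken to be mm^3.
MM3_TIV_THRESHOLD = 100_000.0


class CohortValidationError(ValueError):
    """Raised when a cohort table violates its invariants."""


@dataclass
class CohortTable:
    """Validated per-subject volume table.

    Parameters
    ----------
    data : pandas.DataFrame
        Columns ``subject_id``, ``group``, ``tiv``, one column per VOI
        (ml), plus optional covariate columns.
    atlas : RegionAtlas
        Region catalogue; VOI columns are the columns whose names appear
        in the atlas.
    provenance : str
        Free-text label describing where the table came from.
    group_levels : (str, str)
        ``(reference, comparison)`` group labels.  The sign convention of
        every downstream effect size is *comparison minus reference*, so
        with the default ``("F", "M")`` a positive Cohen's d means M > F.
    """

    data: pd.DataFrame
    atlas: RegionAtlas = field(default_factory=default_atlas)
    provenance: str = ""
    group_levels: tuple[str, str] = ("F", "M")
    #: raw-volume range checks (non-negative, bounded by TIV).  Adjusted
    #: tables (ratios, residuals) may legitimately violate them, so
    #: derived tables switch them off.
    volume_checks: bool = True

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)
        self._validate()

    # -- validation ---------------------------------------------------

    def _validate(self) -> None:
        df = self.data
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise CohortValidationError(f"missing mandatory column {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise CohortValidationError(f"duplicate subject_id {dup!r}")
        levels = set(self.group_levels)
        bad_groups = set(df["group"].unique()) - levels
        if bad_groups:
            raise CohortValidationError(
                f"group labels {sorted(bad_groups)} outside levels {self.group_levels}"
            )
        tiv = df["tiv"].to_numpy(dtype=float)
        if not np.all(np.isfinite(tiv)):
            raise CohortValidationError("non-finite TIV value")
        if np.any(tiv <= 0):
            sid = df.loc[tiv <= 0, "subject_id"].iloc[0]
            raise CohortValidationError(f"non-positive TIV for subject {sid!r}")
        for voi in self.voi_names:
            v = df[voi].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                sid = df.loc[~np.isfinite(v), "subject_id"].iloc[0]
                raise CohortValidationError(
                    f"missing or non-finite volume in {voi!r} for subject {sid!r}"
                )
            if not self.volume_checks:
                continue
            if np.any(v < 0):
                sid = df.loc[v < 0, "subject_id"].iloc[0]
                raise CohortValidationError(f"negative volume in {voi!r} for subject {sid!r}")
            if np.any(v > tiv):
                sid = df.loc[v > tiv, "subject_id"].iloc[0]
                raise CohortValidationError(
                    f"volume in {voi!r} exceeds TIV for subject {sid!r} (unit mismatch?)"
                )

    # -- structure ----------------------------------------------------

    @property
    def voi_names(self) -> list[str]:
        """VOI columns present, in atlas order."""
        present = set(self.data.columns)
        return [n for n in self.atlas.names if n in present]

    @property
    def covariate_names(self) -> list[str]:
        skip = set(MANDATORY_COLUMNS) | set(self.voi_names)
        return sorted(c for c in self.data.columns if c not in skip)

    @property
    def n(self) -> int:
        return len(self.data)

    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {lev: int(counts.get(lev, 0)) for lev in self.group_levels}

    def require_two_groups(self, min_per_group: int = 2) -> None:
        sizes = self.group_sizes()
        small = [lev for lev, n in sizes.items() if n < min_per_group]
        if small:
            raise CohortValidationError(
                f"need at least {min_per_group} subjects per group; "
                f"group(s) {small} too small (sizes {sizes})"
            )

    # -- array views ---------------------------------------------------

    @property
    def tiv(self) -> np.ndarray:
        return self.data["tiv"].to_numpy(dtype=float)

    def voi_matrix(self) -> np.ndarray:
        """Subjects x VOIs volume matrix in atlas column order."""
        return self.data[self.voi_names].to_numpy(dtype=float)

    def comparison_mask(self) -> np.ndarray:
        """Boolean mask of subjects in the comparison group (e.g. males)."""
        return (self.data["group"] == self.group_levels[1]).to_numpy()

    # -- derivation ----------------------------------------------------

    def with_volumes(self, volumes: np.ndarray, provenance: str | None = None) -> "CohortTable":
        """Copy of the cohort with the VOI matrix replaced (adjusted values)."""
        df = self.data.copy()
        df[self.voi_names] = np.asarray(volumes, dtype=float)
        return replace(
            self,
            data=df,
            provenance=self.provenance if provenance is None else provenance,
            volume_checks=False,
        )

    def subset(self, subject_ids, provenance: str | None = None) -> "CohortTable":
        """Row subset by subject id, preserving the given id order."""
        idx = self.data.set_index("subject_id")
        missing = [s for s in subject_ids if s not in idx.index]
        if missing:
            raise KeyError(f"unknown subject ids {missing[:5]}")
        df = idx.loc[list(subject_ids)].reset_index()
        return replace(self, data=df, provenance=self.provenance if provenance is None else provenance)

    def only_group(self, level: str) -> "CohortTable":
        df = self.data[self.data["group"] == level]
        return replace(self, data=df.reset_index(drop=True))


@dataclass
class AdjustedDataset:
    """A cohort tagged with the head-size adjustment that produced it.

    ``method`` is one of ``raw``, ``proportion``, ``pcp``, ``residuals``
    or ``external`` (an adjusted table produced outside the package, e.g.
    an image-space non-linear-modulation pipeline).  ``fit_params`` holds
    the per-VOI parameters of the adjustment: the power-law exponent for
    ``pcp``, the linear slope and grand TIV mean for ``residuals``, and
    nothing for the parameter-free methods.
    """

    table: CohortTable
    method: str
    fit_params: pd.DataFrame | None = None

    VALID_METHODS = ("raw", "proportion", "pcp", "residuals", "external")

    def __post_init__(self) -> None:
        if self.method not in self.VALID_METHODS:
            raise ValueError(f"unknown adjustment method {self.method!r}")
        if self.method == "pcp":
            if self.fit_params is None or "b" not in self.fit_params.columns:
                raise ValueError("pcp dataset requires per-VOI exponents in fit_params")
        if self.method == "residuals":
            need = {"b", "tiv_mean"}
            if self.fit_params is None or not need.issubset(self.fit_params.columns):
                raise ValueError("residuals dataset requires slope and grand TIV mean")


def raw_dataset(cohort: CohortTable) -> AdjustedDataset:
    """Wrap an unadjusted cohort for the comparison suite."""
    return AdjustedDataset(table=cohort, method="raw")


def external_dataset(cohort: CohortTable) -> AdjustedDataset:
    """Ingest an externally adjusted volume table (e.g. image-space output)."""
    return AdjustedDataset(table=cohort, method="external")


# ---------------------------------------------------------------------------
# I/O


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_cohort(
    path,
    atlas: RegionAtlas | None = None,
    *,
    sep: str | None = None,
    group_map: dict[str, str] | None = None,
    group_levels: tuple[str, str] = ("F", "M"),
    provenance: str | None = None,
) -> CohortTable:
    """Read a delimited cohort table.

    The header must name ``subject_id``, ``group`` and ``tiv``; column
    order is irrelevant.  Columns matching atlas region names become VOI
    columns, any others are carried as covariates.  ``group_map`` remaps
    arbitrary labels onto the fixed two-level factor (e.g.
    ``{"female": "F", "male": "M"}``).  Volumes in mm^3 are detected via
    the median TIV and rescaled to ml.
    """
    path = Path(path)
    atlas = atlas if atlas is not None else default_atlas()
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else _infer_sep(path),
        float_precision="round_trip",  # exact read/write round-trips
    )
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise CohortValidationError(f"input file {path} lacks mandatory column {col!r}")
    df["subject_id"] = df["subject_id"].astype(str)
    if group_map:
        df["group"] = df["group"].map(lambda g: group_map.get(g, g))
    tiv = pd.to_numeric(df["tiv"], errors="coerce")
    voi_cols = [c for c in df.columns if c in set(atlas.names)]
    if np.nanmedian(tiv) > MM3_TIV_THRESHOLD:
        logger.warning(
            "median TIV %.0f exceeds %.0f; interpreting volumes as mm^3 and rescaling to ml",
            np.nanmedian(tiv), MM3_TIV_THRESHOLD,
        )
        df["tiv"] = tiv / 1000.0
        for c in voi_cols:
            df[c] = pd.to_numeric(df[c], errors="coerce") / 1000.0
    return CohortTable(
        data=df,
        atlas=atlas,
        provenance=str(path) if provenance is None else provenance,
        group_levels=group_levels,
    )


def write_cohort(table: CohortTable, path) -> None:
    """Write a cohort as delimited text with a deterministic column order.

    Columns come out as ``subject_id``, ``group``, ``tiv``, the VOIs in
    atlas order, then covariates alphabetically.  Numeric fields use the
    shortest round-tripping decimal representation, so read -> write ->
    read is lossless.
    """
    path = Path(path)
    cols = list(MANDATORY_COLUMNS) + table.voi_names + table.covariate_names
    table.data[cols].to_csv(path, sep=_infer_sep(path), index=False)
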