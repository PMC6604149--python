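"""Region catalogue for the AAL-116 parcellation.

The package analyses per-subject tables of regional gray-matter volumes
(VOIs, volumes of interest) defined on the Automated Anatomical Labeling
atlas: 116 named regions, indexed 1-116.  Odd indices are left-hemisphere
regions and even indices their right-hemisphere homologues, except the
eight lobules of the cerebellar vermis (indices 109-116), which are
midline structures.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = ["Region", "RegionAtlas", "default_atlas"]

HEMISPHERES = ("left", "right", "vermis")


@dataclass(frozen=True)
class Region:
    """One atlas entry: 1-based index, region name, hemisphere label."""

    index: int
    name: str
    hemisphere: str


@dataclass(frozen=True)
class RegionAtlas:
    """Ordered catalogue of atlas regions.

    Invariants enforced at construction: unique indices and names, valid
    hemisphere labels, and the index-parity rule (odd = left, even = right)
    for every non-vermis entry.
    """

    regions: tuple[Region, ...]

    def __post_init__(self) -> None:
        indices = [r.index for r in self.regions]
        names = [r.name for r in self.regions]
        if len(set(indices)) != len(indices):
            raise ValueError("atlas indices are not unique")
        if len(set(names)) != len(names):
            raise ValueError("atlas names are not unique")
        for r in self.regions:
            if r.hemisphere not in HEMISPHERES:
                raise ValueError(f"bad hemisphere {r.hemisphere!r} for {r.name}")
            if r.hemisphere == "left" and r.index % 2 == 0:
                raise ValueError(f"left-hemisphere region {r.name} has even index")
            if r.hemisphere == "right" and r.index % 2 == 1:
                raise ValueError(f"right-hemisphere region {r.name} has odd index")

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    @property
    def names(self) -> list[str]:
        """Region names in atlas order."""
        return [r.name for r in self.regions]

    def __getitem__(self, index: int) -> Region:
        """Look a region up by its atlas index (1-based)."""
        for r in self.regions:
            if r.index == index:
                return r
        raise KeyError(index)

    def index_of(self, name: str) -> int:
        for r in self.regions:
            if r.name == name:
                return r.index
        raise KeyError(name)


def default_atlas() -> RegionAtlas:
    """The packaged AAL-116 catalogue.

    Returns the standard AAL ordering (Precentral_L = 1 ... Vermis_10 = 116),
    shipped as a plain-text resource.
    """
    path = resources.files("tivadjust").joinpath("data/aal116.tsv")
    with path.open("r", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        regions = tuple(
            Region(int(row["index"]), row["name"], row["hemisphere"]) for row in reader
        )
    if len(regions) != 116:
        raise RuntimeError("packaged atlas is corrupt")  # pragma: no cover
    return RegionAtlas(regions)
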