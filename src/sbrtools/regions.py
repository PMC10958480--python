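"""Region-of-interest vocabulary shared by the cohort generator, the
phantom builder and the quantification stages.

A :class:`RegionSpec` describes one atlas label: its integer id, a stable
name (used as the column name in SBR panels), hemisphere, dopaminergic
pathway membership, and whether it is a striatal target or part of the
intensity-normalisation reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

HEMISPHERES = ("left", "right", "bilateral")
PATHWAYS = ("nigrostriatal", "mesocorticolimbic", "none")

#: names (without hemisphere prefix) that may carry the striatal flag
_STRIATAL_STEMS = ("dorsal_caudate", "dorsal_putamen", "ventral_striatum")


@dataclass(frozen=True)
class RegionSpec:
    """One labelled region in an atlas / one ROI column in an SBR panel."""

    region_id: int
    name: str
    hemisphere: str = "bilateral"
    pathway: str = "none"
    is_reference: bool = False
    is_striatal: bool = False

    def __post_init__(self) -> None:
        if self.region_id <= 0:
            raise ValueError(f"region_id must be a positive integer, got {self.region_id}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be one of {HEMISPHERES}, got {self.hemisphere!r}")
        if self.pathway not in PATHWAYS:
            raise ValueError(f"pathway must be one of {PATHWAYS}, got {self.pathway!r}")
        if self.is_striatal and not any(s in self.name for s in _STRIATAL_STEMS):
            raise ValueError(
                f"striatal flag only allowed on caudate/putamen/ventral-striatum regions, got {self.name!r}"
            )


def validate_regions(regions: Sequence[RegionSpec]) -> None:
    """Check the atlas-level invariants of a region table.

    Raises ``ValueError`` on duplicate ids or if no reference region is
    flagged (the reference may be a union of several flagged labels,
    e.g. left+right lateral superior occipital).
    """
    ids = [r.region_id for r in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("region_ids must be unique")
    if not any(r.is_reference for r in regions):
        raise ValueError("region table must flag at least one reference region")


# ---------------------------------------------------------------------------
# Default ROI vocabulary: bilateral striatal subdivisions, mesocorticolimbic
# and nigrostriatal cortical targets, and a lateral superior occipital
# reference. Ids are stable so atlases and panels can be regenerated.
# ---------------------------------------------------------------------------

_DEFAULT_ROWS: list[tuple[str, str, str, bool]] = [
    # (stem, pathway, striatal)
    ("dorsal_caudate", "nigrostriatal", True),
    ("dorsal_putamen", "nigrostriatal", True),
    ("ventral_striatum", "nigrostriatal", True),
    ("amygdala", "mesocorticolimbic", False),
    ("hippocampus", "mesocorticolimbic", False),
    ("parahippocampus", "mesocorticolimbic", False),
    ("insula", "mesocorticolimbic", False),
    ("olfactory_cortex", "mesocorticolimbic", False),
    ("anterior_cingulate", "mesocorticolimbic", False),
    ("middle_cingulate", "mesocorticolimbic", False),
    ("postcentral_gyrus", "nigrostriatal", False),
    ("precentral_gyrus", "nigrostriatal", False),
]  # type: ignore[assignment]

REFERENCE_REGION_NAME = "lateral_superior_occipital"


def default_regions() -> list[RegionSpec]:
    """The default bilateral region table (24 target ROIs + 1 reference)."""
    regions: list[RegionSpec] = []
    rid = 1
    for stem, pathway, striatal in _DEFAULT_ROWS:
        for hemi in ("left", "right"):
            regions.append(
                RegionSpec(
                    region_id=rid,
                    name=f"{hemi}_{stem}",
                    hemisphere=hemi,
                    pathway=pathway,
                    is_striatal=striatal,
                )
            )
            rid += 1
    regions.append(
        RegionSpec(
            region_id=rid,
            name=REFERENCE_REGION_NAME,
            hemisphere="bilateral",
            pathway="none",
            is_reference=True,
        )
    )
    validate_regions(regions)
    return regions


def regions_to_frame(regions: Iterable[RegionSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "name": r.name,
                "hemisphere": r.hemisphere,
                "pathway": r.pathway,
                "is_reference": r.is_reference,
                "is_striatal": r.is_striatal,
            }
            for r in regions
        ]
    )


def write_regions(regions: Iterable[RegionSpec], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[RegionSpec]:
    df = pd.read_csv(path, sep="\t")
    required = {"region_id", "name", "hemisphere", "pathway", "is_reference", "is_striatal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region table {path} missing columns: {sorted(missing)}")
    regions = [
        RegionSpec(
            region_id=int(row.region_id),
            name=str(row.name_col),
            hemisphere=str(row.hemisphere),
            pathway=str(row.pathway),
            is_reference=bool(row.is_reference),
            is_striatal=bool(row.is_striatal),
        )
        for row in df.rename(columns={"name": "name_col"}).itertuples(index=False)
    ]
    validate_regions(regions)
    return regions
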