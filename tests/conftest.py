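import numpy as np
import pytest

from sbrtools import (
    CohortConfig,
    GroupSpec,
    LabelAtlas,
    RegionSpec,
    VolumeImage,
    generate_sbr_cohort,
)


@pytest.fixture
def tiny_regions() -> list[RegionSpec]:
    return [
        RegionSpec(1, "left_dorsal_putamen", "left", "nigrostriatal", is_striatal=True),
        RegionSpec(2, "right_dorsal_putamen", "right", "nigrostriatal", is_striatal=True),
        RegionSpec(3, "left_insula", "left", "mesocorticolimbic"),
        RegionSpec(4, "lateral_superior_occipital", "bilateral", "none", is_reference=True),
    ]


@pytest.fixture
def tiny_atlas(tiny_regions) -> LabelAtlas:
    """10x10x10 atlas: three 3x3x3 target blocks and a reference slab."""
    labels = np.zeros((10, 10, 10), dtype=np.int32)
    labels[1:4, 5:8, 1:4] = 1
    labels[6:9, 5:8, 1:4] = 2
    labels[1:4, 5:8, 6:9] = 3
    labels[:, 0:2, :] = 4
    return LabelAtlas(labels=labels, regions=tiny_regions)


@pytest.fixture
def uniform_volume(tiny_atlas) -> VolumeImage:
    """Uptake 100 everywhere; 200/150/100 in regions 1/2/3 (SBR 1, 0.5, 0)."""
    data = np.full((10, 10, 10), 100.0)
    data[tiny_atlas.mask(1)] = 200.0
    data[tiny_atlas.mask(2)] = 150.0
    data[tiny_atlas.mask(3)] = 100.0
    return VolumeImage(data=data)


def two_group_config(
    n_a: int = 30,
    n_b: int = 30,
    rois: tuple[str, ...] = ("roi_a", "roi_b", "roi_c"),
    mean_a: float = 1.0,
    mean_b: float = 1.0,
    sd: float = 0.5,
    partial_corr: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> CohortConfig:
    """Small cross-sectional two-group config used across tests."""
    groups = [
        GroupSpec("A", n_a, {r: mean_a for r in rois}, {r: sd for r in rois}),
        GroupSpec("B", n_b, {r: mean_b for r in rois}, {r: sd for r in rois}),
    ]
    return CohortConfig(
        groups=groups, rois=list(rois), partial_corr=partial_corr or {}, seed=seed, **kwargs
    )


@pytest.fixture
def small_panel():
    return generate_sbr_cohort(two_group_config(seed=7))
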