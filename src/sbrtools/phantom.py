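"""SPECT-like 3-D phantom generation.

Builds a shared label atlas of axis-aligned ellipsoidal target regions plus
a posterior slab reference, then renders one uptake volume per
subject-timepoint of an SBR panel: voxels inside region ``r`` are set to
``(SBR_r + 1) * reference_level``, the reference slab and background sit at
the reference level, and Gaussian smoothing followed by additive Gaussian
noise is applied. The atlas itself is never smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from .cohort import SBRPanel
from .images import LabelAtlas, VolumeImage
from .regions import RegionSpec, validate_regions

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in voxel coordinates."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        d = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, self.center, self.radii))
        return d <= 1.0

    def inside(self, shape: tuple[int, int, int]) -> bool:
        return all(
            c - r >= 0 and c + r <= s - 1 for c, r, s in zip(self.center, self.radii, shape)
        )


@dataclass(frozen=True)
class Slab:
    """Axis-aligned box in voxel coordinates (start inclusive, stop exclusive)."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        sl = tuple(slice(a, b) for a, b in zip(self.start, self.stop))
        m[sl] = True
        return m

    def inside(self, shape: tuple[int, int, int]) -> bool:
        return all(
            0 <= a < b <= s for a, b, s in zip(self.start, self.stop, shape)
        )


@dataclass
class PhantomConfig:
    """Geometry and rendering parameters for a phantom image set."""

    regions: list[RegionSpec]
    geometry: dict[int, Ellipsoid | Slab]  # region_id -> shape spec
    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 3.0
    reference_level: float = 100.0
    fwhm_mm: float = 0.0
    noise_sd_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        validate_regions(self.regions)
        if self.reference_level <= 0:
            raise ValueError("reference_level must be > 0")
        known = {r.region_id for r in self.regions}
        for rid in self.geometry:
            if rid not in known:
                raise ValueError(f"geometry given for unknown region_id {rid}")
        occupancy = np.zeros(self.shape, dtype=np.int8)
        for rid, geom in self.geometry.items():
            if not geom.inside(self.shape):
                raise ValueError(f"region_id {rid} extends outside the grid {self.shape}")
            occupancy += geom.mask(self.shape)
        if (occupancy > 1).any():
            raise ValueError("phantom regions overlap")

    def build_atlas(self) -> LabelAtlas:
        labels = np.zeros(self.shape, dtype=np.int32)
        for rid, geom in self.geometry.items():
            labels[geom.mask(self.shape)] = rid
        vs = (self.voxel_size_mm,) * 3
        return LabelAtlas(labels=labels, regions=list(self.regions), voxel_size=vs)


@dataclass
class PhantomSet:
    """Shared atlas plus one rendered volume per panel row."""

    atlas: LabelAtlas
    volumes: list[VolumeImage]
    subject_ids: list[str]
    timepoints: list[str]
    groups: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[str, str, VolumeImage]]:
        return iter(zip(self.subject_ids, self.timepoints, self.volumes))


def generate_phantom_images(config: PhantomConfig, cohort: SBRPanel) -> PhantomSet:
    """Render one phantom volume per subject-timepoint row of ``cohort``.

    Every ROI column of the panel must have geometry in ``config``
    (reference and unmapped atlas regions excepted).
    """
    config.validate()
    atlas = config.build_atlas()
    name_to_id = {r.name: r.region_id for r in config.regions}
    ref_ids = set(atlas.reference_ids)
    target_rois = [c for c in cohort.roi_columns]
    for roi in target_rois:
        rid = name_to_id.get(roi)
        if rid is None or (rid not in config.geometry and rid not in ref_ids):
            raise ValueError(f"panel ROI {roi!r} has no geometry in the phantom config")
    masks = {roi: atlas.mask(name_to_id[roi]) for roi in target_rois}
    sigma_vox = config.fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm
    rng = np.random.default_rng(config.seed)
    vs = (config.voxel_size_mm,) * 3

    volumes: list[VolumeImage] = []
    for _, row in cohort.data.iterrows():
        vol = np.full(config.shape, config.reference_level, dtype=float)
        for roi in target_rois:
            vol[masks[roi]] = (float(row[roi]) + 1.0) * config.reference_level
        if sigma_vox > 0:
            vol = ndimage.gaussian_filter(vol, sigma=sigma_vox)
        if config.noise_sd_frac > 0:
            vol = vol + rng.normal(
                0.0, config.noise_sd_frac * config.reference_level, size=config.shape
            )
        volumes.append(VolumeImage(data=vol, voxel_size=vs))
    return PhantomSet(
        atlas=atlas,
        volumes=volumes,
        subject_ids=list(cohort.data["subject_id"]),
        timepoints=list(cohort.data["timepoint"]),
        groups=list(cohort.data["group"]),
    )


def default_phantom_config(
    regions: Sequence[RegionSpec],
    shape: tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float = 3.0,
    radius_vox: float = 5.0,
    reference_level: float = 100.0,
    fwhm_mm: float = 0.0,
    noise_sd_frac: float = 0.0,
    seed: int = 0,
) -> PhantomConfig:
    """Deterministic non-overlapping layout: target ellipsoids on a lattice
    in the anterior part of the grid, reference regions as a posterior slab
    (split along x when more than one label is flagged)."""
    targets = [r for r in regions if not r.is_reference]
    refs = [r for r in regions if r.is_reference]
    if not refs:
        raise ValueError("region list must include a reference region")
    spacing = int(np.ceil(2 * radius_vox + 3))
    margin = int(np.ceil(radius_vox + 1))
    # lattice positions, keeping y >= ~1/3 of the grid free for the slab
    y_min = margin + shape[1] // 4
    xs = list(range(margin, shape[0] - margin, spacing))
    ys = list(range(y_min, shape[1] - margin, spacing))
    zs = list(range(margin, shape[2] - margin, spacing))
    positions = [(x, y, z) for z in zs for y in ys for x in xs]
    if len(positions) < len(targets):
        raise ValueError(
            f"grid {shape} too small for {len(targets)} regions at radius {radius_vox}"
        )
    geometry: dict[int, Ellipsoid | Slab] = {}
    for spec, pos in zip(targets, positions):
        geometry[spec.region_id] = Ellipsoid(
            center=tuple(float(v) for v in pos), radii=(radius_vox,) * 3
        )
    # posterior slab (low y), split along x across the flagged reference labels
    slab_y = (2, max(3, shape[1] // 8))
    x_edges = np.linspace(2, shape[0] - 2, len(refs) + 1).astype(int)
    for i, spec in enumerate(refs):
        geometry[spec.region_id] = Slab(
            start=(int(x_edges[i]), slab_y[0], 2),
            stop=(int(x_edges[i + 1]), slab_y[1], shape[2] - 2),
        )
    cfg = PhantomConfig(
        regions=list(regions),
        geometry=geometry,
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        reference_level=reference_level,
        fwhm_mm=fwhm_mm,
        noise_sd_frac=noise_sd_frac,
        seed=seed,
    )
    cfg.validate()
    return cfg
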