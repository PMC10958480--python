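"""Specific binding ratio (SBR) quantification.

SBR = mean(target) / mean(reference) - 1, the semi-quantitative
DAT-availability measure. The reference is the union of all atlas regions
flagged ``is_reference`` (by default the lateral superior occipital
labels). NaN voxels are excluded from every mean; negative voxels are
retained (reconstruction artifacts) with a warning when they exceed 1% of
a region. No partial-volume correction is applied.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .images import LabelAtlas, VolumeImage


def _masked_mean(data: np.ndarray, mask: np.ndarray, what: str) -> float:
    vals = data[mask]
    if vals.size == 0:
        raise ValueError(f"{what}: region is empty")
    finite = vals[np.isfinite(vals)]
    if finite.size == 0:
        raise ValueError(f"{what}: region has no finite voxels")
    neg_frac = np.mean(finite < 0)
    if neg_frac > 0.01:
        warnings.warn(
            f"{what}: {neg_frac:.1%} of voxels are negative", UserWarning, stacklevel=3
        )
    return float(finite.mean())


def regional_mean(volume: VolumeImage, atlas: LabelAtlas, region_id: int) -> float:
    """Arithmetic mean uptake over the finite voxels of one region."""
    atlas.check_paired(volume)
    region = atlas.region(region_id)
    return _masked_mean(volume.data, atlas.mask(region_id), f"region {region.name!r}")


def reference_mean(volume: VolumeImage, atlas: LabelAtlas) -> float:
    """Mean uptake over the reference-region union; must be positive."""
    atlas.check_paired(volume)
    m = _masked_mean(volume.data, atlas.reference_mask(), "reference region")
    if m <= 0:
        raise ValueError(f"reference mean must be positive, got {m}")
    return m


def compute_sbr(volume: VolumeImage, atlas: LabelAtlas) -> pd.DataFrame:
    """Per-region SBR table.

    Returns a DataFrame with columns ``region``, ``n_voxels``,
    ``mean_uptake``, ``sbr``. Reference regions appear with SBR 0 by
    construction.
    """
    atlas.check_paired(volume)
    ref = reference_mean(volume, atlas)
    ref_ids = set(atlas.reference_ids)
    rows = []
    for spec in atlas.regions:
        mask = atlas.mask(spec.region_id)
        n = int(mask.sum())
        if n == 0:
            continue
        mean = _masked_mean(volume.data, mask, f"region {spec.name!r}")
        sbr = 0.0 if spec.region_id in ref_ids else mean / ref - 1.0
        rows.append({"region": spec.name, "n_voxels": n, "mean_uptake": mean, "sbr": sbr})
    return pd.DataFrame(rows)


def parametric_sbr_image(volume: VolumeImage, atlas: LabelAtlas) -> VolumeImage:
    """Voxel-wise SBR map: every voxel v becomes v / mean(reference) - 1.

    Spatial metadata is preserved; the regional mean of the output over any
    region equals that region's SBR from :func:`compute_sbr`.
    """
    ref = reference_mean(volume, atlas)
    return volume.with_data(volume.data / ref - 1.0)
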