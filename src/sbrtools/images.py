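"""Volume and atlas containers with NIfTI-1 I/O.

These are deliberately thin: a float 3-D grid plus voxel size and an
opaque affine for :class:`VolumeImage`, and an integer label grid plus a
region table for :class:`LabelAtlas`. No resampling is performed anywhere;
a volume and its atlas must share shape exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

from .regions import RegionSpec, read_regions, validate_regions, write_regions


def _default_affine(voxel_size: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


@dataclass
class VolumeImage:
    """A 3-D uptake grid (arbitrary units) with spatial metadata."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.any(np.isfinite(self.data)):
            raise ValueError("volume has no finite voxels")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """Same spatial metadata, new voxel values."""
        return VolumeImage(data=data, voxel_size=self.voxel_size, affine=self.affine.copy())

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            voxel_size=zooms,
            affine=np.asarray(img.affine),
        )


@dataclass
class LabelAtlas:
    """Integer-labelled parcellation (0 = background) with a region table."""

    labels: np.ndarray
    regions: list[RegionSpec] = field(default_factory=list)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            lab = np.rint(self.labels).astype(np.int32)
            if not np.allclose(lab, self.labels):
                raise ValueError("atlas labels must be integers")
            self.labels = lab
        if self.labels.ndim != 3:
            raise ValueError(f"atlas must be 3-D, got shape {self.labels.shape}")
        if self.affine is None:
            self.affine = _default_affine(self.voxel_size)
        validate_regions(self.regions)
        present = set(np.unique(self.labels)) - {0}
        known = {r.region_id for r in self.regions}
        unknown = present - known
        if unknown:
            raise ValueError(f"labels present in atlas but absent from region table: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def region(self, region_id: int) -> RegionSpec:
        for r in self.regions:
            if r.region_id == region_id:
                return r
        raise KeyError(f"region_id {region_id} not in region table")

    def mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    @property
    def reference_ids(self) -> list[int]:
        return [r.region_id for r in self.regions if r.is_reference]

    def reference_mask(self) -> np.ndarray:
        """Union of all regions flagged as reference."""
        ids = self.reference_ids
        if not ids:
            raise ValueError("atlas has no reference region")
        return np.isin(self.labels, ids)

    def striatal_mask(self) -> np.ndarray:
        ids = [r.region_id for r in self.regions if r.is_striatal]
        if not ids:
            raise ValueError("atlas region table has no striatal flags")
        return np.isin(self.labels, ids)

    def check_paired(self, volume: VolumeImage) -> None:
        if volume.shape != self.shape:
            raise ValueError(
                f"volume shape {volume.shape} does not match atlas shape {self.shape}; "
                "resampling is not performed"
            )

    def to_nifti(self, path: str | Path, regions_path: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path))
        if regions_path is not None:
            write_regions(self.regions, regions_path)

    @classmethod
    def from_nifti(cls, path: str | Path, regions: Sequence[RegionSpec] | str | Path) -> "LabelAtlas":
        img = nib.load(str(path))
        if isinstance(regions, (str, Path)):
            regions = read_regions(regions)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(
            labels=np.asarray(img.dataobj),
            regions=list(regions),
            voxel_size=zooms,
            affine=np.asarray(img.affine),
        )
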