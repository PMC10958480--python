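"""Single-subject voxel-wise depletion screening.

One scan is compared against a control sample voxel by voxel with the
single-case t-test (Crawford-Howell form, algebraically identical to a
two-sample t with one observation in the patient group), suprathreshold
voxels are grouped into connected components, and the scan is classified
as showing significant striatal depletion when a retained cluster overlaps
a striatal atlas label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import LabelAtlas, VolumeImage

DIRECTIONS = ("less", "greater", "two-sided")

#: connectivity code -> binary structure for connected-component labelling
_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: np.ones((3, 3, 3), dtype=bool),
}


@dataclass
class StatMap:
    """Voxel-wise t map with p-values for a stated direction."""

    t: np.ndarray
    p: np.ndarray
    df: float
    direction: str = "less"
    mask: np.ndarray | None = None  # True where the voxel was analysed


def p_from_t(t: np.ndarray, df: float, direction: str) -> np.ndarray:
    if direction == "less":
        return stats.t.cdf(t, df)
    if direction == "greater":
        return stats.t.sf(t, df)
    if direction == "two-sided":
        return 2.0 * stats.t.sf(np.abs(t), df)
    raise ValueError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def single_case_t_map(
    subject: VolumeImage,
    controls: list[VolumeImage],
    direction: str = "less",
    mask_frac: float | None = 0.1,
) -> StatMap:
    """Voxel-wise single-case t of one scan against a control sample.

    t = (x - mean_HC) / (s_HC * sqrt(1 + 1/n_HC)), df = n_HC - 1. The
    default direction ``less`` yields one-sided p for depletion
    (subject below controls). Voxels where the control mean falls below
    ``mask_frac`` times the global control mean are excluded (set
    ``mask_frac=None`` to analyse everything); masked or zero-variance
    voxels get t = NaN, p = 1.
    """
    if len(controls) < 3:
        raise ValueError(f"need at least 3 control volumes, got {len(controls)}")
    shapes = {c.shape for c in controls} | {subject.shape}
    if len(shapes) != 1:
        raise ValueError(f"subject/control shapes differ: {sorted(shapes)}")
    hc = np.stack([c.data for c in controls])
    n = hc.shape[0]
    m = hc.mean(axis=0)
    s = hc.std(axis=0, ddof=1)
    if mask_frac is not None:
        mask = m > mask_frac * m.mean()
    else:
        mask = np.ones(subject.shape, dtype=bool)
    valid = mask & (s > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (subject.data - m) / (s * np.sqrt(1.0 + 1.0 / n))
    t = np.where(valid, t, np.nan)
    df = n - 1
    p = np.ones_like(t)
    p[valid] = p_from_t(t[valid], df, direction)
    return StatMap(t=t, p=p, df=df, direction=direction, mask=valid)


@dataclass
class ClusterSet:
    """Retained suprathreshold clusters of a :class:`StatMap`."""

    labels: np.ndarray  # int map, 0 = no cluster, clusters numbered from 1
    table: pd.DataFrame  # cluster_id, size, peak_t, peak_x, peak_y, peak_z
    p_threshold: float
    min_extent: int
    connectivity: int

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    @property
    def total_volume(self) -> int:
        return int(self.table["size"].sum()) if len(self.table) else 0


def label_suprathreshold(supra: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Connected components of a boolean map (6/18/26-neighbour)."""
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}, got {connectivity}")
    return ndimage.label(supra, structure=_STRUCTURES[connectivity])


def threshold_clusters(
    stat_map: StatMap,
    p_threshold: float = 0.05,
    min_extent: int = 100,
    connectivity: int = 26,
) -> ClusterSet:
    """Group voxels with p < ``p_threshold`` into connected components and
    retain those strictly larger than ``min_extent`` voxels."""
    if not (0.0 < p_threshold < 1.0):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    if min_extent < 1:
        raise ValueError(f"min_extent must be >= 1, got {min_extent}")
    supra = np.asarray(stat_map.p < p_threshold)
    lab, n_raw = label_suprathreshold(supra, connectivity)
    out = np.zeros_like(lab)
    rows = []
    next_id = 1
    # magnitude of t in the tested direction, for the peak
    peak_stat = np.abs(stat_map.t) if stat_map.direction == "two-sided" else (
        -stat_map.t if stat_map.direction == "less" else stat_map.t
    )
    for cid in range(1, n_raw + 1):
        comp = lab == cid
        size = int(comp.sum())
        if size <= min_extent:
            continue
        vals = np.where(comp & np.isfinite(stat_map.t), peak_stat, -np.inf)
        peak = np.unravel_index(int(np.argmax(vals)), vals.shape)
        rows.append(
            {
                "cluster_id": next_id,
                "size": size,
                "peak_t": float(stat_map.t[peak]),
                "peak_x": int(peak[0]),
                "peak_y": int(peak[1]),
                "peak_z": int(peak[2]),
            }
        )
        out[comp] = next_id
        next_id += 1
    table = pd.DataFrame(
        rows, columns=["cluster_id", "size", "peak_t", "peak_x", "peak_y", "peak_z"]
    )
    return ClusterSet(
        labels=out,
        table=table,
        p_threshold=p_threshold,
        min_extent=min_extent,
        connectivity=connectivity,
    )


@dataclass
class ScreeningReport:
    """Outcome of striatal depletion screening for one scan."""

    positive: bool
    clusters: pd.DataFrame  # cluster table + striatal_overlap_voxels

    def to_frame(self) -> pd.DataFrame:
        df = self.clusters.copy()
        df["decision"] = "positive" if self.positive else "negative"
        if df.empty:
            df = pd.DataFrame(
                [{"cluster_id": 0, "size": 0, "peak_t": np.nan, "striatal_overlap_voxels": 0,
                  "decision": "negative"}]
            )
        return df


def classify_depletion(clusters: ClusterSet, atlas: LabelAtlas) -> ScreeningReport:
    """Positive iff any retained cluster overlaps a striatal label by >= 1 voxel."""
    striatal = atlas.striatal_mask()  # raises if no striatal flags
    if clusters.labels.shape != striatal.shape:
        raise ValueError("cluster map and atlas shapes differ")
    overlaps = []
    for cid in clusters.table["cluster_id"]:
        overlaps.append(int(np.sum((clusters.labels == cid) & striatal)))
    table = clusters.table.copy()
    table["striatal_overlap_voxels"] = overlaps
    positive = any(o >= 1 for o in overlaps)
    return ScreeningReport(positive=positive, clusters=table)


def screen_subject(
    subject: VolumeImage,
    controls: list[VolumeImage],
    atlas: LabelAtlas,
    p_threshold: float = 0.05,
    min_extent: int = 100,
    connectivity: int = 26,
    direction: str = "less",
    mask_frac: float | None = 0.1,
) -> ScreeningReport:
    """Full screening pipeline: t map -> cluster threshold -> classification."""
    smap = single_case_t_map(subject, controls, direction=direction, mask_frac=mask_frac)
    clusters = threshold_clusters(smap, p_threshold, min_extent, connectivity)
    return classify_depletion(clusters, atlas)
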