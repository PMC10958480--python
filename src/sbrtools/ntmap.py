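"""Neurotransmitter-template spatial correlation.

Region-level patient-vs-control alteration z-scores are rank-correlated
(Spearman) with normative template values (e.g. DAT, SERT) over the shared
ROI vocabulary; inference uses a group-label permutation null with
Benjamini-Hochberg adjustment across templates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASELINE, SBRPanel

MIN_SHARED_REGIONS = 5


@dataclass
class TemplateMap:
    """Region -> template value over the panel's ROI vocabulary."""

    name: str
    values: pd.Series  # index = region names

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError(f"template {self.name!r} has non-finite values")

    @classmethod
    def from_tsv(cls, path: str | Path, name: str | None = None) -> "TemplateMap":
        df = pd.read_csv(path, sep="\t")
        if not {"region", "value"} <= set(df.columns):
            raise ValueError(f"template file {path} must have columns 'region' and 'value'")
        return cls(name=name or Path(path).stem, values=df.set_index("region")["value"])

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename("value").rename_axis("region").reset_index().to_csv(
            path, sep="\t", index=False
        )


def region_zscores(
    panel: SBRPanel,
    patient_group: str,
    control_group: str,
    timepoint: str = BASELINE,
) -> pd.Series:
    """Per-region alteration z: (mean_patient - mean_control) / SD_control.

    Regions with zero control SD are dropped with a warning.
    """
    pat = panel.select(group=patient_group, timepoint=timepoint)
    ctl = panel.select(group=control_group, timepoint=timepoint)
    if len(pat) < 3 or len(ctl) < 3:
        raise ValueError("both groups need n >= 3")
    rois = panel.roi_columns
    pm = pat[rois].mean(axis=0)
    cm = ctl[rois].mean(axis=0)
    cs = ctl[rois].std(axis=0, ddof=1)
    zero = cs == 0
    if zero.any():
        warnings.warn(
            f"dropping regions with zero control SD: {list(cs.index[zero])}",
            UserWarning,
            stacklevel=2,
        )
    z = (pm - cm) / cs
    return z[~zero]


def spatial_spearman(z: pd.Series, template: TemplateMap) -> float:
    """Spearman rank correlation (average-rank ties) over shared regions."""
    shared = z.index.intersection(template.values.index)
    if len(shared) < MIN_SHARED_REGIONS:
        raise ValueError(
            f"only {len(shared)} shared regions; need >= {MIN_SHARED_REGIONS}"
        )
    tv = template.values.loc[shared].to_numpy()
    if np.ptp(tv) == 0:
        raise ValueError(f"template {template.name!r} is constant over shared regions")
    rho = stats.spearmanr(z.loc[shared].to_numpy(), tv).statistic
    return float(rho)


@dataclass
class SpatialCorrResult:
    """Spearman correlation of an alteration z map with one template."""

    template: str
    rho: float
    p_perm: float
    p_adj: float
    n_regions: int
    n_perm: int
    seed: int
    zscores: pd.Series


def permutation_test(
    panel: SBRPanel,
    patient_group: str,
    control_group: str,
    templates: list[TemplateMap],
    n_perm: int = 1000,
    seed: int = 0,
    timepoint: str = BASELINE,
) -> list[SpatialCorrResult]:
    """Group-label permutation test of the template correlations.

    The null permutes patient/control labels, recomputing the z vector and
    Spearman rho each time; p = (1 + #{|rho*| >= |rho|}) / (n_perm + 1)
    (two-sided). Adjusted p is Benjamini-Hochberg across the supplied
    templates. Deterministic given ``seed``.
    """
    from statsmodels.stats.multitest import multipletests

    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    df = panel.select(timepoint=timepoint)
    df = df[df["group"].isin([patient_group, control_group])]
    rois = panel.roi_columns
    X = df[rois].to_numpy(dtype=float)
    is_pat = (df["group"] == patient_group).to_numpy()
    n_pat = int(is_pat.sum())
    n_tot = len(df)
    if n_pat < 3 or n_tot - n_pat < 3:
        raise ValueError("both groups need n >= 3")

    n_distinct = math.comb(n_tot, n_pat)
    z_obs = region_zscores(panel, patient_group, control_group, timepoint=timepoint)
    obs = {t.name: spatial_spearman(z_obs, t) for t in templates}

    # pre-extract shared-region template arrays aligned to the z index
    aligned = {}
    for t in templates:
        shared = z_obs.index.intersection(t.values.index)
        cols = [rois.index(r) for r in shared]
        aligned[t.name] = (np.array(cols), t.values.loc[shared].to_numpy())

    rng = np.random.default_rng(seed)
    if n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct label assignments (< {n_perm}); using all",
            UserWarning,
            stacklevel=2,
        )
        from itertools import combinations

        assignments = []
        for idx in combinations(range(n_tot), n_pat):
            lab = np.zeros(n_tot, dtype=bool)
            lab[list(idx)] = True
            assignments.append(lab)
    else:
        assignments = [rng.permutation(is_pat) for _ in range(n_perm)]

    exceed = {t.name: 0 for t in templates}
    for lab in assignments:
        pat, ctl = X[lab], X[~lab]
        cm = ctl.mean(axis=0)
        cs = ctl.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_star = (pat.mean(axis=0) - cm) / cs
        for t in templates:
            cols, tv = aligned[t.name]
            zv = z_star[cols]
            ok = np.isfinite(zv)
            if ok.sum() < MIN_SHARED_REGIONS:
                continue
            rho_star = stats.spearmanr(zv[ok], tv[ok]).statistic
            if abs(rho_star) >= abs(obs[t.name]) - 1e-12:
                exceed[t.name] += 1

    m = len(assignments)
    p_perm = {name: (1 + c) / (m + 1) for name, c in exceed.items()}
    names = [t.name for t in templates]
    p_adj = multipletests([p_perm[n] for n in names], method="fdr_bh")[1]
    results = []
    for name, adj in zip(names, p_adj):
        shared_n = len(aligned[name][0])
        results.append(
            SpatialCorrResult(
                template=name,
                rho=obs[name],
                p_perm=p_perm[name],
                p_adj=float(adj),
                n_regions=shared_n,
                n_perm=m,
                seed=seed,
                zscores=z_obs,
            )
        )
    return results
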