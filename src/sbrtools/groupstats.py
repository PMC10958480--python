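"""Group-level statistics: voxel-wise GLM contrasts with permutation
cluster-FWE correction, paired difference maps, ROI-level (M)ANCOVA, and
the two-timepoint longitudinal group contrast.

Cluster-level family-wise error is controlled by permutation of the
maximum cluster extent (Freedman-Lane residual permutation when nuisance
covariates are present); random-field corrections are intentionally not
implemented.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASELINE, FOLLOWUP, SBRPanel
from .images import VolumeImage
from .screen import StatMap, label_suprathreshold, p_from_t


@dataclass
class DesignMatrix:
    """OLS design: rows = subjects (aligned with the volume list), plus the
    contrast vector to test."""

    X: np.ndarray
    columns: list[str]
    contrast: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.contrast = np.asarray(self.contrast, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.columns):
            raise ValueError("design shape does not match column names")
        if self.contrast.shape != (self.X.shape[1],):
            raise ValueError("contrast length does not match design columns")
        if not np.any(self.contrast != 0):
            raise ValueError("contrast vector is all zeros")
        rank = np.linalg.matrix_rank(self.X)
        if rank < self.X.shape[1]:
            collinear = _collinear_columns(self.X, self.columns)
            raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def df(self) -> int:
        return self.X.shape[0] - self.X.shape[1]

    def nuisance_columns(self) -> np.ndarray:
        """Indices of columns with zero contrast weight (reduced model)."""
        return np.flatnonzero(self.contrast == 0)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns whose removal restores full rank."""
    full_rank = np.linalg.matrix_rank(X)
    out = []
    for j, name in enumerate(names):
        sub = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            out.append(name)
    return out or list(names)


def design_two_groups(
    group_labels: list[str] | np.ndarray,
    contrast_groups: tuple[str, str],
    covariates: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Intercept + indicator(group == contrast_groups[0]) + covariates; the
    contrast tests group A minus group B."""
    labels = np.asarray(group_labels)
    a, b = contrast_groups
    keep = np.isin(labels, [a, b])
    if not keep.all():
        raise ValueError("group_labels contain entries outside the contrast groups")
    indicator = (labels == a).astype(float)
    cols = [np.ones(len(labels)), indicator]
    names = ["intercept", f"group[{a}-{b}]"]
    if covariates is not None:
        for c in covariates.columns:
            v = covariates[c].to_numpy(dtype=float)
            if np.ptp(v) == 0:
                warnings.warn(f"dropping constant covariate {c!r}", UserWarning, stacklevel=2)
                continue
            cols.append(v)
            names.append(c)
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[1] = 1.0
    return DesignMatrix(X=X, columns=names, contrast=contrast)


def _stack(volumes: list[VolumeImage] | np.ndarray) -> tuple[np.ndarray, tuple[int, ...]]:
    if isinstance(volumes, np.ndarray):
        arr = volumes
    else:
        arr = np.stack([v.data for v in volumes])
    shape = arr.shape[1:]
    return arr.reshape(arr.shape[0], -1), shape


def _glm_t(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, int]:
    """Vectorised OLS t statistic of one contrast over many voxels."""
    n, k = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - k
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    var_c = float(contrast @ xtx_inv @ contrast)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (contrast @ beta) / np.sqrt(sigma2 * var_c)
    return t, df


def glm_contrast_map(
    volumes: list[VolumeImage] | np.ndarray,
    design: DesignMatrix,
    direction: str = "two-sided",
) -> StatMap:
    """Voxel-wise OLS fit and t statistic for the design's contrast."""
    Y, shape = _stack(volumes)
    if Y.shape[0] != design.n:
        raise ValueError(f"{Y.shape[0]} volumes but design has {design.n} rows")
    if design.df < 1:
        raise ValueError("no residual degrees of freedom")
    t, df = _glm_t(Y, design.X, design.contrast)
    valid = np.isfinite(t)
    p = np.ones_like(t)
    p[valid] = p_from_t(t[valid], df, direction)
    return StatMap(
        t=t.reshape(shape), p=p.reshape(shape), df=df, direction=direction,
        mask=valid.reshape(shape),
    )


@dataclass
class ClusterFweResult:
    """Observed clusters with permutation cluster-FWE p-values."""

    stat_map: StatMap
    clusters: pd.DataFrame  # cluster_id, size, peak_t, fwe_p
    cluster_forming_p: float
    n_perm: int
    seed: int
    null_max_extents: np.ndarray = field(repr=False, default=None)
    labels: np.ndarray = field(repr=False, default=None)


def _cluster_extents(p: np.ndarray, thresh: float, connectivity: int) -> tuple[np.ndarray, list[int]]:
    lab, n = label_suprathreshold(p < thresh, connectivity)
    sizes = ndimage_sum(lab, n)
    return lab, sizes


def ndimage_sum(lab: np.ndarray, n: int) -> list[int]:
    if n == 0:
        return []
    return list(np.bincount(lab.ravel(), minlength=n + 1)[1:].astype(int))


def cluster_fwe(
    volumes: list[VolumeImage] | np.ndarray,
    design: DesignMatrix,
    n_perm: int = 1000,
    cluster_forming_p: float = 0.005,
    direction: str = "two-sided",
    connectivity: int = 26,
    seed: int = 0,
) -> ClusterFweResult:
    """Permutation cluster-extent FWE for a GLM contrast.

    Observed clusters are formed at voxel ``p < cluster_forming_p``; the
    null distribution of the maximum cluster extent is built by
    Freedman-Lane permutation (rows of the reduced-model residuals are
    permuted, the reduced fit added back, and the full-model t map
    recomputed). Cluster FWE p = (1 + #{max_extent* >= extent}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    Y, shape = _stack(volumes)
    n = Y.shape[0]
    observed = glm_contrast_map(Y.reshape((n,) + shape), design, direction=direction)
    lab, sizes = _cluster_extents(observed.p, cluster_forming_p, connectivity)

    # Freedman-Lane: reduced model = nuisance (zero-contrast) columns
    Z = design.X[:, design.nuisance_columns()]
    if Z.size:
        gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
        fitted = Z @ gamma
    else:
        fitted = np.zeros_like(Y)
    resid = Y - fitted

    rng = np.random.default_rng(seed)
    n_distinct = math.factorial(n) if n <= 20 else None
    perms: list[np.ndarray]
    if n_distinct is not None and n_distinct <= n_perm:
        warnings.warn(
            f"only {n_distinct} distinct permutations available (< {n_perm}); using all",
            UserWarning,
            stacklevel=2,
        )
        perms = [np.asarray(p) for p in itertools.permutations(range(n))]
    else:
        perms = [rng.permutation(n) for _ in range(n_perm)]

    max_extents = np.zeros(len(perms), dtype=int)
    df = design.df
    for i, perm in enumerate(perms):
        Yp = fitted + resid[perm]
        t, _ = _glm_t(Yp, design.X, design.contrast)
        valid = np.isfinite(t)
        p = np.ones_like(t)
        p[valid] = p_from_t(t[valid], df, direction)
        _, null_sizes = _cluster_extents(p.reshape(shape), cluster_forming_p, connectivity)
        max_extents[i] = max(null_sizes) if null_sizes else 0

    m = len(perms)
    rows = []
    order = np.argsort(sizes)[::-1]
    for new_id, idx in enumerate(order, start=1):
        size = sizes[idx]
        fwe_p = (1 + int(np.sum(max_extents >= size))) / (m + 1)
        comp = lab == (idx + 1)
        tvals = np.where(comp, observed.t, np.nan)
        peak = np.nanmax(np.abs(tvals))
        rows.append({"cluster_id": new_id, "size": int(size), "peak_t": float(peak), "fwe_p": fwe_p})
    relabeled = np.zeros_like(lab)
    for new_id, idx in enumerate(order, start=1):
        relabeled[lab == (idx + 1)] = new_id
    clusters = pd.DataFrame(rows, columns=["cluster_id", "size", "peak_t", "fwe_p"])
    return ClusterFweResult(
        stat_map=observed,
        clusters=clusters,
        cluster_forming_p=cluster_forming_p,
        n_perm=m,
        seed=seed,
        null_max_extents=max_extents,
        labels=relabeled,
    )


def paired_t_map(
    volumes_baseline: list[VolumeImage] | np.ndarray,
    volumes_followup: list[VolumeImage] | np.ndarray,
    subjects_baseline: list[str] | None = None,
    subjects_followup: list[str] | None = None,
    direction: str = "two-sided",
) -> StatMap:
    """One-sample t on per-subject difference images (followup - baseline)."""
    if subjects_baseline is not None or subjects_followup is not None:
        if list(subjects_baseline) != list(subjects_followup):
            raise ValueError("baseline and follow-up subject lists do not match")
    Yb, shape = _stack(volumes_baseline)
    Yf, shape_f = _stack(volumes_followup)
    if Yb.shape != Yf.shape:
        raise ValueError("baseline and follow-up volume stacks differ in shape")
    n = Yb.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired volumes, got {n}")
    D = Yf - Yb
    mean = D.mean(axis=0)
    sd = D.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)  # identical images -> t = 0
    df = n - 1
    finite = np.isfinite(t)
    p = np.where(t > 0, 0.0, 1.0) if direction != "two-sided" else np.zeros_like(t)
    p[finite] = p_from_t(t[finite], df, direction)
    p[~finite & (sd == 0)] = 0.0  # constant nonzero shift: degenerate, flagged by inf t
    return StatMap(t=t.reshape(shape), p=p.reshape(shape), df=df, direction=direction,
                   mask=finite.reshape(shape))


# ---------------------------------------------------------------------------
# ROI-level statistics on SBR panels
# ---------------------------------------------------------------------------

def roi_ancova(
    panel: SBRPanel,
    roi: str,
    covariates: tuple[str, ...] = ("age", "sex", "updrs3"),
    groups: tuple[str, str] | None = None,
    timepoint: str = BASELINE,
) -> dict:
    """Group effect on one ROI's SBR adjusted for nuisance covariates (OLS).

    Returns t (two groups) or F (multi-group), p, residual df, and
    covariate-adjusted group means (predictions at the pooled covariate
    means). Constant covariates are dropped with a warning.
    """
    import statsmodels.api as sm

    df = panel.select(timepoint=timepoint)
    if groups is not None:
        df = df[df["group"].isin(groups)]
    labels = sorted(df["group"].unique())
    if len(labels) < 2:
        raise ValueError(f"need >= 2 groups, got {labels}")
    y = df[roi].to_numpy(dtype=float)
    n = len(y)
    cols = {"intercept": np.ones(n)}
    for g in labels[1:]:
        cols[f"group[{g}]"] = (df["group"] == g).to_numpy(dtype=float)
    used_covs = []
    for c in covariates:
        v = df[c]
        v = (v == "F").astype(float).to_numpy() if v.dtype == object else v.to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"dropping constant covariate {c!r}", UserWarning, stacklevel=2)
            continue
        cols[c] = v
        used_covs.append(c)
    if n <= len(used_covs) + 2:
        raise ValueError("too few subjects for the requested covariates")
    X = pd.DataFrame(cols)
    fit = sm.OLS(y, X).fit()
    group_cols = [c for c in X.columns if c.startswith("group[")]
    # adjusted means: predict at pooled covariate means
    cov_means = {c: float(X[c].mean()) for c in used_covs}
    adjusted = {}
    for g in labels:
        row = {"intercept": 1.0, **{gc: 0.0 for gc in group_cols}, **cov_means}
        if g != labels[0]:
            row[f"group[{g}]"] = 1.0
        adjusted[g] = float(fit.predict(pd.DataFrame([row])[X.columns])[0])
    out = {"roi": roi, "groups": labels, "df_resid": float(fit.df_resid),
           "adjusted_means": adjusted, "covariates": used_covs}
    if len(labels) == 2:
        name = group_cols[0]
        out["t"] = float(fit.tvalues[name])
        out["p"] = float(fit.pvalues[name])
        out["estimate"] = float(fit.params[name])
    else:
        R = [[1.0 if c == gc else 0.0 for c in X.columns] for gc in group_cols]
        ftest = fit.f_test(R)
        out["F"] = float(ftest.fvalue)
        out["p"] = float(ftest.pvalue)
    return out


def roi_ancova_table(
    panel: SBRPanel,
    rois: list[str] | None = None,
    covariates: tuple[str, ...] = ("age", "sex", "updrs3"),
    groups: tuple[str, str] | None = None,
    timepoint: str = BASELINE,
    bh_adjust: bool = True,
) -> pd.DataFrame:
    """Per-ROI ANCOVA table; raw p-values plus an optional BH column."""
    rois = rois or panel.roi_columns
    rows = []
    for roi in rois:
        res = roi_ancova(panel, roi, covariates=covariates, groups=groups, timepoint=timepoint)
        rows.append({
            "roi": roi,
            "stat": res.get("t", res.get("F")),
            "p": res["p"],
            **{f"adj_mean[{g}]": m for g, m in res["adjusted_means"].items()},
        })
    out = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def mancova(
    panel: SBRPanel,
    rois: list[str],
    covariates: tuple[str, ...] = ("age", "sex", "updrs3"),
    groups: tuple[str, str] | None = None,
    timepoint: str = BASELINE,
) -> dict:
    """Multivariate group test (Wilks' lambda with F approximation) across a
    named ROI set, adjusted for covariates."""
    from statsmodels.multivariate.manova import MANOVA

    df = panel.select(timepoint=timepoint).copy()
    if groups is not None:
        df = df[df["group"].isin(groups)]
    if df["group"].nunique() < 2:
        raise ValueError("need >= 2 groups")
    df["sex_num"] = (df["sex"] == "F").astype(float)
    terms = ["C(group)"]
    for c in covariates:
        terms.append("sex_num" if c == "sex" else c)
    formula = " + ".join([f"Q('{r}')" for r in rois]) + " ~ " + " + ".join(terms)
    mv = MANOVA.from_formula(formula, data=df)
    res = mv.mv_test()
    stat = res.results["C(group)"]["stat"]
    wilks = stat.loc["Wilks' lambda"]
    return {
        "wilks_lambda": float(wilks["Value"]),
        "F": float(wilks["F Value"]),
        "df_num": float(wilks["Num DF"]),
        "df_den": float(wilks["Den DF"]),
        "p": float(wilks["Pr > F"]),
    }


def longitudinal_group_contrast(
    panel: SBRPanel,
    roi: str,
    groups: tuple[str, str],
) -> dict:
    """Group difference in SBR change scores (follow-up minus baseline).

    Two-sample pooled t on per-subject change scores. At two timepoints
    this equals the group-by-time interaction of a random-intercept mixed
    model exactly, so it stands in for the mixed-model trajectory test.
    Subjects missing a timepoint are listwise dropped (count reported).
    """
    changes = {}
    dropped = 0
    for g in groups:
        bl = panel.select(group=g, timepoint=BASELINE).set_index("subject_id")[roi]
        fu = panel.select(group=g, timepoint=FOLLOWUP).set_index("subject_id")[roi]
        shared = bl.index.intersection(fu.index)
        dropped += (len(bl.index.union(fu.index)) - len(shared))
        if len(shared) < 3:
            raise ValueError(f"group {g!r}: fewer than 3 subjects with both timepoints")
        changes[g] = (fu.loc[shared] - bl.loc[shared]).to_numpy(dtype=float)
    a, b = groups
    t, p = stats.ttest_ind(changes[a], changes[b], equal_var=True)
    est = float(changes[a].mean() - changes[b].mean())
    if changes[a].std(ddof=1) == 0 and changes[b].std(ddof=1) == 0 and est == 0:
        t, p = 0.0, 1.0
    return {
        "roi": roi,
        "estimate": est,
        "t": float(t),
        "p": float(p),
        "df": len(changes[a]) + len(changes[b]) - 2,
        "n": {a: len(changes[a]), b: len(changes[b])},
        "n_dropped": int(dropped),
    }
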