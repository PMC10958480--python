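"""Synthetic SBR cohort generator.

Draws group-structured subject-by-ROI panels of specific binding ratios
(SBR) with a planted partial-correlation (precision) structure, optional
two-timepoint longitudinal trajectories with within-subject coupling, and
demographic/clinical covariates. Replaces access-controlled patient data
for testing and calibration of every downstream stage.

All randomness flows from a single seeded :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

BASELINE = "baseline"
FOLLOWUP = "followup"
TIMEPOINTS = (BASELINE, FOLLOWUP)

#: metadata columns of an SBR panel, in canonical order
METADATA_COLUMNS = ("subject_id", "group", "timepoint", "age", "sex", "updrs3")


class PanelParseError(ValueError):
    """Raised when a panel file cannot be parsed; names the offending cell."""


# ---------------------------------------------------------------------------
# Default per-ROI SBR parameters (mean, SD) for the simulated groups at
# baseline and two-year follow-up. HC has no published regional values; by
# convention the synthetic HC mean is the SWEDD baseline mean inflated by
# +10% with the SWEDD SD, flat over time. Override via CohortConfig.
# ---------------------------------------------------------------------------

#: roi -> {group -> (baseline_mean, baseline_sd, followup_mean, followup_sd)}
DEFAULT_SBR_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "left_dorsal_caudate": {"PD": (1.34, 0.43, 1.01, 0.44), "SWEDD": (1.59, 0.55, 1.69, 0.58)},
    "right_dorsal_caudate": {"PD": (1.44, 0.45, 1.15, 0.47), "SWEDD": (1.77, 0.70, 1.72, 0.61)},
    "left_dorsal_putamen": {"PD": (1.34, 0.48, 0.98, 0.37), "SWEDD": (2.33, 0.73, 2.29, 0.55)},
    "right_dorsal_putamen": {"PD": (1.33, 0.49, 1.03, 0.44), "SWEDD": (2.25, 0.74, 2.34, 0.50)},
    "left_ventral_striatum": {"PD": (1.16, 0.44, 0.85, 0.36), "SWEDD": (1.52, 0.54, 1.60, 0.59)},
    "right_ventral_striatum": {"PD": (1.22, 0.47, 0.87, 0.37), "SWEDD": (1.50, 0.59, 1.63, 0.60)},
    "left_amygdala": {"PD": (0.31, 0.16, 0.33, 0.17), "SWEDD": (0.56, 0.48, 0.48, 0.19)},
    "right_amygdala": {"PD": (0.36, 0.20, 0.29, 0.16), "SWEDD": (0.53, 0.50, 0.49, 0.19)},
    "left_hippocampus": {"PD": (0.29, 0.11, 0.29, 0.10), "SWEDD": (0.47, 0.35, 0.41, 0.12)},
    "right_hippocampus": {"PD": (0.30, 0.12, 0.29, 0.12), "SWEDD": (0.46, 0.33, 0.41, 0.14)},
    "left_parahippocampus": {"PD": (0.16, 0.10, 0.17, 0.11), "SWEDD": (0.34, 0.45, 0.25, 0.10)},
    "right_parahippocampus": {"PD": (0.17, 0.12, 0.15, 0.12), "SWEDD": (0.31, 0.50, 0.24, 0.11)},
    "left_insula": {"PD": (0.36, 0.14, 0.29, 0.13), "SWEDD": (0.47, 0.21, 0.50, 0.21)},
    "right_insula": {"PD": (0.34, 0.11, 0.29, 0.10), "SWEDD": (0.45, 0.16, 0.48, 0.19)},
    "left_olfactory_cortex": {"PD": (0.38, 0.22, 0.31, 0.24), "SWEDD": (0.48, 0.24, 0.47, 0.30)},
    "right_olfactory_cortex": {"PD": (0.39, 0.24, 0.30, 0.23), "SWEDD": (0.48, 0.28, 0.44, 0.27)},
    "left_anterior_cingulate": {"PD": (0.21, 0.10, 0.17, 0.11), "SWEDD": (0.18, 0.15, 0.18, 0.12)},
    "right_anterior_cingulate": {"PD": (0.22, 0.10, 0.18, 0.11), "SWEDD": (0.17, 0.14, 0.20, 0.13)},
    "left_middle_cingulate": {"PD": (0.25, 0.12, 0.21, 0.12), "SWEDD": (0.28, 0.11, 0.29, 0.13)},
    "right_middle_cingulate": {"PD": (0.25, 0.12, 0.23, 0.12), "SWEDD": (0.29, 0.12, 0.30, 0.15)},
    "left_postcentral_gyrus": {"PD": (0.07, 0.07, 0.04, 0.06), "SWEDD": (0.05, 0.06, 0.05, 0.06)},
    "right_postcentral_gyrus": {"PD": (0.06, 0.05, 0.05, 0.07), "SWEDD": (0.06, 0.07, 0.06, 0.07)},
    "left_precentral_gyrus": {"PD": (0.15, 0.11, 0.14, 0.11), "SWEDD": (0.16, 0.10, 0.16, 0.11)},
    "right_precentral_gyrus": {"PD": (0.16, 0.12, 0.15, 0.12), "SWEDD": (0.17, 0.12, 0.16, 0.11)},
}

HC_INFLATION = 1.10  # synthetic HC mean = SWEDD baseline mean * 1.10

DEFAULT_AGE_MEAN = 63.4
DEFAULT_AGE_SD = 8.2
DEFAULT_FEMALE_PROP = 0.37
DEFAULT_RHO_T = 0.7

DEFAULT_UPDRS3 = {"PD": (18.5, 6.87), "SWEDD": (15.1, 9.11), "HC": (1.0, 1.0)}
DEFAULT_GROUP_N = {"PD": 49, "SWEDD": 36, "HC": 49}


@dataclass
class GroupSpec:
    """Per-group generator parameters.

    ``followup_means`` of ``None`` makes the group cross-sectional
    (baseline rows only).
    """

    label: str
    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    followup_means: Mapping[str, float] | None = None
    followup_sds: Mapping[str, float] | None = None
    updrs3_mean: float = 10.0
    updrs3_sd: float = 5.0


@dataclass
class CohortConfig:
    """Full configuration of a synthetic cohort draw."""

    groups: list[GroupSpec]
    rois: list[str]
    #: per-group symmetric matrix of target partial correlations
    #: (len(rois) x len(rois), zeros for absent edges); None -> independence
    partial_corr: dict[str, np.ndarray] = field(default_factory=dict)
    rho_t: float = DEFAULT_RHO_T
    age_mean: float = DEFAULT_AGE_MEAN
    age_sd: float = DEFAULT_AGE_SD
    female_prop: float = DEFAULT_FEMALE_PROP
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("config needs at least one group")
        if not (0.0 <= self.rho_t < 1.0):
            raise ValueError(f"rho_t must lie in [0, 1), got {self.rho_t}")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels")
        for g in self.groups:
            if g.n < 4:
                raise ValueError(f"group {g.label!r}: n must be >= 4, got {g.n}")
            for roi in self.rois:
                if roi not in g.means or roi not in g.sds:
                    raise ValueError(f"group {g.label!r}: missing mean/SD for ROI {roi!r}")
                if g.sds[roi] <= 0:
                    raise ValueError(f"group {g.label!r}: SD for {roi!r} must be > 0")
            if g.followup_means is not None:
                for roi in self.rois:
                    if roi not in g.followup_means:
                        raise ValueError(f"group {g.label!r}: missing follow-up mean for {roi!r}")
        p = len(self.rois)
        for label, pc in self.partial_corr.items():
            pc = np.asarray(pc, dtype=float)
            if pc.shape != (p, p):
                raise ValueError(f"partial_corr[{label!r}] must be {p}x{p}, got {pc.shape}")
            if not np.allclose(pc, pc.T):
                raise ValueError(f"partial_corr[{label!r}] must be symmetric")
            off = pc[~np.eye(p, dtype=bool)]
            if np.any(np.abs(off) >= 1):
                raise ValueError(f"partial_corr[{label!r}] entries must lie in (-1, 1)")


class SBRPanel:
    """Subject-by-ROI matrix of SBR values with group/timepoint metadata.

    Thin wrapper over a :class:`pandas.DataFrame` whose first columns are
    :data:`METADATA_COLUMNS` and whose remaining columns are ROI SBRs.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)
        self.validate()

    @property
    def roi_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in METADATA_COLUMNS]

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def validate(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise PanelParseError(f"panel missing metadata columns: {missing}")
        if not self.roi_columns:
            raise PanelParseError("panel has no ROI columns")
        dup = self.data.duplicated(subset=["subject_id", "timepoint"])
        if dup.any():
            rows = self.data.loc[dup, ["subject_id", "timepoint"]].iloc[0]
            raise PanelParseError(
                f"duplicated (subject, timepoint) pair: ({rows.subject_id}, {rows.timepoint})"
            )
        for col in self.roi_columns:
            vals = self.data[col]
            if not np.issubdtype(vals.dtype, np.number):
                bad = vals[pd.to_numeric(vals, errors="coerce").isna()]
                raise PanelParseError(
                    f"non-numeric SBR cell at row {bad.index[0]}, column {col!r}: {bad.iloc[0]!r}"
                )
            if not np.all(np.isfinite(vals.to_numpy(dtype=float))):
                idx = int(np.flatnonzero(~np.isfinite(vals.to_numpy(dtype=float)))[0])
                raise PanelParseError(f"non-finite SBR at row {idx}, column {col!r}")
        if self.data["group"].isna().any() or (self.data["group"] == "").any():
            raise PanelParseError("empty group labels")

    def select(self, group: str | None = None, timepoint: str | None = None) -> pd.DataFrame:
        df = self.data
        if group is not None:
            df = df[df["group"] == group]
        if timepoint is not None:
            df = df[df["timepoint"] == timepoint]
        return df

    def values(self, rois: Sequence[str], group: str, timepoint: str = BASELINE) -> np.ndarray:
        """(n_subjects, len(rois)) SBR matrix for one group/timepoint."""
        df = self.select(group=group, timepoint=timepoint)
        missing = [r for r in rois if r not in df.columns]
        if missing:
            raise KeyError(f"panel lacks ROI columns: {missing}")
        return df[list(rois)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SBRPanel) and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# correlation structure from a planted partial-correlation matrix
# ---------------------------------------------------------------------------

def correlation_from_partial(pc: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a target partial-correlation matrix.

    Builds the precision matrix with unit diagonal and off-diagonal
    ``-pc_ij``, inverts it, and rescales the inverse to unit diagonal. A
    non-positive-definite precision is repaired by adding ``eps * I`` with
    the smallest ``eps`` in ``{1e-8 * 2**k}`` that lifts the minimum
    eigenvalue above 1e-10 (with a warning).
    """
    pc = np.asarray(pc, dtype=float)
    p = pc.shape[0]
    prec = -pc.copy()
    np.fill_diagonal(prec, 1.0)
    min_eig = float(np.linalg.eigvalsh(prec)[0])
    if min_eig <= 1e-10:
        eps = 1e-8
        while min_eig + eps <= 1e-10:
            eps *= 2.0
            if eps > 1e6:
                raise ValueError(
                    "partial-correlation structure is not positive definite and "
                    "could not be repaired (precision matrix too indefinite)"
                )
        warnings.warn(
            f"precision matrix not positive definite (min eigenvalue {min_eig:.3g}); "
            f"repaired by adding {eps:.3g} * I",
            UserWarning,
            stacklevel=2,
        )
        prec = prec + eps * np.eye(p)
    cov = np.linalg.inv(prec)
    d = np.sqrt(np.diag(cov))
    corr = cov / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr


def generate_sbr_cohort(config: CohortConfig) -> SBRPanel:
    """Draw a synthetic SBR panel from a :class:`CohortConfig`.

    Per group, baseline ROI vectors are multivariate normal with the
    configured means and covariance ``D R D`` (``D`` = diag of SDs, ``R``
    the correlation implied by the planted partial-correlation structure).
    Longitudinal groups draw baseline and follow-up jointly with
    within-subject correlation ``rho_t``. Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rois = list(config.rois)
    p = len(rois)
    rows: list[pd.DataFrame] = []
    for g in config.groups:
        # sub-generator per group so adding a group never perturbs others
        grng = np.random.default_rng(rng.integers(0, 2**63 - 1))
        pc = config.partial_corr.get(g.label)
        try:
            R = correlation_from_partial(pc) if pc is not None else np.eye(p)
        except ValueError as err:
            raise ValueError(f"group {g.label!r}: {err}") from err
        mu_bl = np.array([g.means[r] for r in rois])
        sd_bl = np.array([g.sds[r] for r in rois])
        longitudinal = g.followup_means is not None
        if longitudinal:
            fu_sds = g.followup_sds if g.followup_sds is not None else g.sds
            mu_fu = np.array([g.followup_means[r] for r in rois])
            sd_fu = np.array([fu_sds[r] for r in rois])
            T = np.array([[1.0, config.rho_t], [config.rho_t, 1.0]])
            corr2 = np.kron(T, R)  # (2p x 2p), ordering [bl rois..., fu rois...]
            d = np.concatenate([sd_bl, sd_fu])
            cov = corr2 * np.outer(d, d)
            mean = np.concatenate([mu_bl, mu_fu])
        else:
            cov = R * np.outer(sd_bl, sd_bl)
            mean = mu_bl
        draws = grng.multivariate_normal(mean, cov, size=g.n, method="cholesky")
        age = grng.normal(config.age_mean, config.age_sd, size=g.n)
        sex = np.where(grng.random(g.n) < config.female_prop, "F", "M")
        updrs = grng.normal(g.updrs3_mean, g.updrs3_sd, size=g.n)
        sid = [f"{g.label}-{i:04d}" for i in range(g.n)]
        base = pd.DataFrame(
            {
                "subject_id": sid,
                "group": g.label,
                "timepoint": BASELINE,
                "age": age,
                "sex": sex,
                "updrs3": updrs,
            }
        )
        rows.append(pd.concat([base, pd.DataFrame(draws[:, :p], columns=rois)], axis=1))
        if longitudinal:
            fu = base.copy()
            fu["timepoint"] = FOLLOWUP
            rows.append(pd.concat([fu, pd.DataFrame(draws[:, p:], columns=rois)], axis=1))
    return SBRPanel(pd.concat(rows, ignore_index=True))


# ---------------------------------------------------------------------------
# default cohort emulating the published group parameters
# ---------------------------------------------------------------------------

def default_hc_params() -> dict[str, tuple[float, float]]:
    """Synthetic HC (mean, SD) per ROI: SWEDD baseline mean * 1.10, SWEDD SD."""
    return {
        roi: (params["SWEDD"][0] * HC_INFLATION, params["SWEDD"][1])
        for roi, params in DEFAULT_SBR_PARAMS.items()
    }


def default_cohort_config(
    n_pd: int = DEFAULT_GROUP_N["PD"],
    n_swedd: int = DEFAULT_GROUP_N["SWEDD"],
    n_hc: int = DEFAULT_GROUP_N["HC"],
    longitudinal: bool = True,
    rho_t: float = DEFAULT_RHO_T,
    seed: int = 0,
) -> CohortConfig:
    """PD/SWEDD/HC cohort parameterised from the default SBR table."""
    rois = list(DEFAULT_SBR_PARAMS)
    groups = []
    for label, n in (("PD", n_pd), ("SWEDD", n_swedd), ("HC", n_hc)):
        if n <= 0:
            continue
        if label == "HC":
            hc = default_hc_params()
            means = {r: hc[r][0] for r in rois}
            sds = {r: hc[r][1] for r in rois}
            fu_means = dict(means) if longitudinal else None
        else:
            means = {r: DEFAULT_SBR_PARAMS[r][label][0] for r in rois}
            sds = {r: DEFAULT_SBR_PARAMS[r][label][1] for r in rois}
            fu_means = (
                {r: DEFAULT_SBR_PARAMS[r][label][2] for r in rois} if longitudinal else None
            )
        fu_sds = (
            {r: DEFAULT_SBR_PARAMS[r][label][3] for r in rois}
            if longitudinal and label != "HC"
            else (dict(sds) if longitudinal else None)
        )
        u_mean, u_sd = DEFAULT_UPDRS3[label]
        groups.append(
            GroupSpec(
                label=label,
                n=n,
                means=means,
                sds=sds,
                followup_means=fu_means,
                followup_sds=fu_sds,
                updrs3_mean=u_mean,
                updrs3_sd=u_sd,
            )
        )
    return CohortConfig(groups=groups, rois=rois, rho_t=rho_t, seed=seed)


# ---------------------------------------------------------------------------
# panel I/O (TSV, full precision)
# ---------------------------------------------------------------------------

def write_cohort(panel: SBRPanel, path: str | Path) -> None:
    """Write a panel to TSV with full float precision (lossless round trip)."""
    panel.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cohort(path: str | Path) -> SBRPanel:
    """Read a TSV panel written by :func:`write_cohort`.

    Raises :class:`PanelParseError` naming the offending row/column on
    malformed headers or non-numeric SBR cells.
    """
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str, "sex": str},
        float_precision="round_trip",
    )
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise PanelParseError(f"panel file {path} missing columns: {missing}")
    for col in df.columns:
        if col in METADATA_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise PanelParseError(
                f"non-numeric SBR cell at row {row}, column {col!r}: {df[col].iloc[row]!r}"
            )
        df[col] = coerced
    return SBRPanel(df)
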