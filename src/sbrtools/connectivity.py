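"""Molecular connectivity: per-group partial-correlation networks over
pathway ROI sets, Fisher-z edge comparison between groups, alteration
percentages, and the network-level chi-square contrast.

"Partial correlation" here is the full partial correlation: each ROI pair
is conditioned on all remaining network nodes (k = p - 2), obtained from
the normalised inverse of the sample correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import BASELINE, SBRPanel


@dataclass(frozen=True)
class NetworkDefinition:
    """Named, ordered ROI set (bilateral entries listed left then right)."""

    name: str
    nodes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) < 3:
            raise ValueError(f"network {self.name!r} needs >= 3 nodes, got {len(self.nodes)}")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError(f"network {self.name!r} has duplicate nodes")


def default_networks() -> dict[str, NetworkDefinition]:
    """Default node sets for the two dopaminergic pathways (configurable;
    node membership is configuration, not an assumption baked into code)."""

    def lr(*stems: str) -> tuple[str, ...]:
        return tuple(f"{h}_{s}" for s in stems for h in ("left", "right"))

    return {
        "nigrostriatal": NetworkDefinition(
            "nigrostriatal",
            lr("dorsal_caudate", "dorsal_putamen", "ventral_striatum",
               "precentral_gyrus", "postcentral_gyrus"),
        ),
        "mesocorticolimbic": NetworkDefinition(
            "mesocorticolimbic",
            lr("ventral_striatum", "anterior_cingulate", "middle_cingulate",
               "olfactory_cortex", "insula", "amygdala", "hippocampus",
               "parahippocampus"),
        ),
    }


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def partial_corr_matrix(X: np.ndarray, use_pinv: bool = False) -> np.ndarray:
    """Full partial correlations from the normalised inverse correlation
    matrix: r_ij = -Omega_ij / sqrt(Omega_ii * Omega_jj)."""
    R = np.corrcoef(X, rowvar=False)
    if use_pinv:
        omega = np.linalg.pinv(R)
    else:
        if np.linalg.cond(R) > 1e12:
            raise np.linalg.LinAlgError(
                "sample correlation matrix is singular or near-singular; "
                "pass use_pinv=True to fall back to the pseudo-inverse"
            )
        omega = np.linalg.inv(R)
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 1.0)
    return np.clip(pc, -1.0, 1.0)


def partial_corr_residualization(X: np.ndarray) -> np.ndarray:
    """Independent oracle: partial correlation of each pair as the Pearson
    correlation of the OLS residuals of each variable regressed on all
    remaining variables. O(p^2) regressions; used for verification."""
    n, p = X.shape
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            others = [c for c in range(p) if c not in (i, j)]
            Z = np.column_stack([np.ones(n), X[:, others]])
            ri = X[:, i] - Z @ np.linalg.lstsq(Z, X[:, i], rcond=None)[0]
            rj = X[:, j] - Z @ np.linalg.lstsq(Z, X[:, j], rcond=None)[0]
            r = float(np.corrcoef(ri, rj)[0, 1])
            out[i, j] = out[j, i] = r
    return out


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilising transform z = atanh(r); |r| must be < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("|r| must be < 1 for Fisher's z (z is infinite at |r| = 1)")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def z_variance(n: int, k: int) -> float:
    """Sampling variance of Fisher z for a partial correlation controlling
    k variables: 1 / (n - k - 3)."""
    if n - k - 3 <= 0:
        raise ValueError(f"need n - k - 3 > 0, got n={n}, k={k}")
    return 1.0 / (n - k - 3)


@dataclass
class PartialCorrNetwork:
    """Estimated network for one group."""

    definition: NetworkDefinition
    group: str
    r: np.ndarray  # p x p partial correlations
    z: np.ndarray  # Fisher z, NaN on the diagonal
    p_values: np.ndarray  # per-edge two-tailed p, NaN on the diagonal
    n: int

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.definition.nodes

    @property
    def k(self) -> int:
        return len(self.nodes) - 2

    def edges(self) -> pd.DataFrame:
        rows = []
        nodes = self.nodes
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                rows.append({
                    "node_i": nodes[i], "node_j": nodes[j],
                    "r": self.r[i, j], "z": self.z[i, j], "p": self.p_values[i, j],
                })
        return pd.DataFrame(rows)


def partial_corr_network(
    panel: SBRPanel,
    net: NetworkDefinition,
    group: str,
    timepoint: str = BASELINE,
    use_pinv: bool = False,
) -> PartialCorrNetwork:
    """Estimate one group's partial-correlation network.

    Per-edge significance uses t = r * sqrt((n - 2 - k) / (1 - r^2)) with
    df = n - 2 - k, two-tailed, where k = p - 2 controlled nodes.
    """
    X = panel.values(net.nodes, group=group, timepoint=timepoint)
    n, p = X.shape
    if n < p + 3:
        raise ValueError(
            f"group {group!r} has n={n} subjects; need n >= p + 3 = {p + 3} "
            f"for a {p}-node network"
        )
    r = partial_corr_matrix(X, use_pinv=use_pinv)
    k = p - 2
    df = n - 2 - k
    off = ~np.eye(p, dtype=bool)
    z = np.full((p, p), np.nan)
    pv = np.full((p, p), np.nan)
    rr = np.clip(r[off], -0.9999999999, 0.9999999999)
    z[off] = np.arctanh(rr)
    with np.errstate(divide="ignore"):
        tstat = rr * np.sqrt(df / (1.0 - rr**2))
    pv[off] = 2.0 * stats.t.sf(np.abs(tstat), df)
    return PartialCorrNetwork(definition=net, group=group, r=r, z=z, p_values=pv, n=n)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

@dataclass
class EdgeComparisonSet:
    """Edge-wise Z-test results between two groups (A = patient group,
    B = reference group) plus network-level summary counts."""

    network: str
    group_a: str
    group_b: str
    edges: pd.DataFrame  # node_i, node_j, z_a, z_b, Z, p, altered, direction
    n_a: int
    n_b: int
    alpha: float

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_altered(self) -> int:
        return int(self.edges["altered"].sum())

    @property
    def pct_altered(self) -> float:
        return 100.0 * self.n_altered / self.n_edges

    @property
    def pct_increases(self) -> float:
        """Of the altered edges, the percentage that are increases in A."""
        alt = self.edges[self.edges["altered"]]
        if len(alt) == 0:
            return float("nan")
        return 100.0 * float((alt["direction"] == "increase").mean())

    def summary(self) -> dict:
        return {
            "network": self.network,
            "groups": f"{self.group_a} vs {self.group_b}",
            "n_edges": self.n_edges,
            "n_altered": self.n_altered,
            "pct_altered": self.pct_altered,
            "pct_increases": self.pct_increases,
        }


def compare_networks(
    net_a: PartialCorrNetwork,
    net_b: PartialCorrNetwork,
    alpha: float = 0.01,
    k_correction: bool = True,
    restrict_to_significant: bool = False,
    within_alpha: float = 0.01,
) -> EdgeComparisonSet:
    """Edge-wise Fisher-z Z-test between two estimated networks.

    Z = (z_A - z_B) / sqrt(var_A + var_B) with var = 1/(n - k - 3) when
    ``k_correction`` (default) or 1/(n - 3) otherwise; two-tailed p; an
    edge is altered iff p < ``alpha``. ``net_a`` is treated as the patient
    group, so direction = increase when z_A > z_B on altered edges.
    ``restrict_to_significant`` limits the comparison to edges significant
    within either group at ``within_alpha``.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks have different node sets or ordering")
    p = len(net_a.nodes)
    k = (p - 2) if k_correction else 0
    var = z_variance(net_a.n, k) + z_variance(net_b.n, k)
    rows = []
    for i in range(p):
        for j in range(i + 1, p):
            if restrict_to_significant and not (
                net_a.p_values[i, j] < within_alpha or net_b.p_values[i, j] < within_alpha
            ):
                continue
            za, zb = net_a.z[i, j], net_b.z[i, j]
            Z = (za - zb) / np.sqrt(var)
            pval = 2.0 * stats.norm.sf(abs(Z))
            altered = bool(pval < alpha)
            rows.append({
                "node_i": net_a.nodes[i], "node_j": net_a.nodes[j],
                "z_a": za, "z_b": zb, "Z": Z, "p": pval, "altered": altered,
                "direction": ("increase" if za > zb else "decrease") if altered else "",
            })
    edges = pd.DataFrame(rows)
    return EdgeComparisonSet(
        network=net_a.definition.name,
        group_a=net_a.group,
        group_b=net_b.group,
        edges=edges,
        n_a=net_a.n,
        n_b=net_b.n,
        alpha=alpha,
    )


def chi2_alteration_compare(altered_a: int, altered_b: int, n_edges: int) -> dict:
    """Pearson chi-square (1 df, no continuity correction) comparing the
    altered-edge proportions of two groups over the same edge count."""
    if n_edges <= 0:
        raise ValueError("n_edges must be > 0")
    for name, a in (("altered_a", altered_a), ("altered_b", altered_b)):
        if not (0 <= a <= n_edges):
            raise ValueError(f"{name}={a} outside [0, {n_edges}]")
    obs = np.array([
        [altered_a, n_edges - altered_a],
        [altered_b, n_edges - altered_b],
    ], dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected < 1).any():
        warnings.warn(
            "expected cell count < 1; consider an exact test", UserWarning, stacklevel=2
        )
    if (expected == 0).any():
        return {"chi2": 0.0, "p": 1.0}
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1))}
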