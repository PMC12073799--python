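"""Proportional thresholding, weighted graph measures and AUC comparisons.

Networks are proportionally thresholded over a sparsity range (default 0.05
to 0.13 in steps of 0.01) so that every network retains the same density;
each measure is evaluated at every threshold and summarized by the area
under its metric-vs-sparsity curve (trapezoidal rule). Group differences in
AUC are tested per measure with two-sample tests (Student/Welch t or
Mann-Whitney U, chosen by D'Agostino-Pearson normality and F variance
tests) under Holm-Sidak correction across the measure family.

Conventions for FA-weighted networks: shortest-path edge length is the
reciprocal of the weight (strong connections are short); global efficiency
is the harmonic form (mean of inverse distances, so disconnected pairs
contribute zero); clustering is the Onnela geometric-mean variant;
betweenness is expressed as the percentage of shortest paths through a
node.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import dijkstra
from statsmodels.stats.multitest import multipletests

from .synthetic import Cohort, Connectome


@dataclass
class AnalysisConfig:
    """Analysis parameters shared across the pipeline."""

    sparsity_min: float = 0.05
    sparsity_max: float = 0.13
    sparsity_step: float = 0.01
    gamma: float = 1.2
    nbs_permutations: int = 5000
    nbs_thresholds: tuple[int, ...] = (2, 3, 4, 5)
    consensus_fraction: float = 0.5
    novelty_min_count: int = 2
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.sparsity_min <= self.sparsity_max < 1):
            raise ValueError("require 0 < sparsity_min <= sparsity_max < 1")
        if self.sparsity_step <= 0:
            raise ValueError("sparsity_step must be positive")

    @property
    def sparsity_grid(self) -> np.ndarray:
        n = int(round((self.sparsity_max - self.sparsity_min) / self.sparsity_step))
        return self.sparsity_min + self.sparsity_step * np.arange(n + 1)


def _as_matrix(network) -> np.ndarray:
    """Accept a Connectome, ConsensusConnectome or bare array."""
    W = getattr(network, "weights", network)
    return np.asarray(W, dtype=float)


# ---------------------------------------------------------------------------
# Thresholding
# ---------------------------------------------------------------------------


def threshold_by_sparsity(network, s: float) -> np.ndarray:
    """Keep the ``k = round(s * n(n-1)/2)`` strongest edges, zero the rest.

    ``round`` is banker's rounding (round-half-even). Ties at the cutoff
    weight are broken deterministically by (i, j) node-index order. If the
    network has fewer than k nonzero edges it is returned unchanged, with a
    warning.
    """
    if not 0 < s < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    W = _as_matrix(network)
    n = W.shape[0]
    k = round(s * n * (n - 1) / 2)
    iu, ju = np.triu_indices(n, k=1)
    w = W[iu, ju]
    nonzero = np.flatnonzero(w > 0)
    if k >= nonzero.size:
        if k > nonzero.size:
            warnings.warn(
                f"requested {k} edges but only {nonzero.size} nonzero edges "
                "available; keeping all",
                stacklevel=2,
            )
        return W.copy()
    # stable sort on (-weight, i, j): upper-triangle order is already (i, j)
    order = nonzero[np.argsort(-w[nonzero], kind="stable")]
    keep = order[:k]
    out = np.zeros_like(W)
    out[iu[keep], ju[keep]] = w[keep]
    return out + out.T


# ---------------------------------------------------------------------------
# Node and network measures
# ---------------------------------------------------------------------------


def node_strength(network) -> np.ndarray:
    """Per-node sum of incident edge weights."""
    return _as_matrix(network).sum(axis=1)


def network_density(network) -> float:
    """Fraction of possible edges present."""
    W = _as_matrix(network)
    n = W.shape[0]
    if n < 2:
        return 0.0
    return float((np.count_nonzero(W) / 2) / (n * (n - 1) / 2))


#: Weights below this are treated as absent in shortest-path computations
#: (their reciprocal lengths would overflow and corrupt path counting).
MIN_PATH_WEIGHT = 1e-12


def _length_graph(W: np.ndarray) -> nx.Graph:
    """networkx graph with reciprocal-weight 'length' attribute on edges."""
    G = nx.Graph()
    G.add_nodes_from(range(W.shape[0]))
    iu, ju = np.nonzero(np.triu(W, k=1) > MIN_PATH_WEIGHT)
    G.add_weighted_edges_from(
        (int(i), int(j), float(W[i, j])) for i, j in zip(iu, ju)
    )
    for _, _, d in G.edges(data=True):
        d["length"] = 1.0 / d["weight"]
    return G


def node_betweenness(network) -> np.ndarray:
    """Percentage of all shortest paths between node pairs passing through
    each node, with shortest paths under reciprocal-weight edge lengths.
    Isolated nodes and disconnected pairs contribute zero."""
    W = _as_matrix(network)
    G = _length_graph(W)
    bc = nx.betweenness_centrality(G, weight="length", normalized=True)
    return 100.0 * np.array([bc[v] for v in range(W.shape[0])])


def clustering_coefficient(network) -> np.ndarray:
    """Weighted clustering per node (Onnela geometric-mean-of-triangles
    variant, weights normalized by the network maximum); zero for nodes of
    degree < 2."""
    W = _as_matrix(network)
    G = _length_graph(W)
    cc = nx.clustering(G, weight="weight")
    return np.array([cc[v] for v in range(W.shape[0])])


def _distance_matrix(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances under length = 1/weight."""
    n = W.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    present = W > MIN_PATH_WEIGHT
    with np.errstate(divide="ignore"):
        L = np.where(present, 1.0 / np.where(present, W, 1.0), 0.0)
    return dijkstra(sp.csr_matrix(L), directed=False)


def global_efficiency(network) -> float:
    """Harmonic-mean global efficiency: average over ordered node pairs of
    the inverse shortest-path distance (1/inf = 0 for disconnected
    pairs)."""
    W = _as_matrix(network)
    n = W.shape[0]
    if n < 2:
        return 0.0
    D = _distance_matrix(W)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(D) & (D > 0), 1.0 / np.where(D > 0, D, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(network) -> np.ndarray:
    """Per-node local efficiency: the global efficiency of the subgraph
    induced by the node's neighbors (zero for degree < 2)."""
    W = _as_matrix(network)
    n = W.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nbrs = np.flatnonzero(W[v] > 0)
        if nbrs.size < 2:
            continue
        out[v] = global_efficiency(W[np.ix_(nbrs, nbrs)])
    return out


#: Named network summary measures: each maps a weight matrix to a scalar.
NETWORK_MEASURES = {
    "global_efficiency": global_efficiency,
    "strength": lambda W: float(node_strength(W).mean()),
    "betweenness": lambda W: float(node_betweenness(W).mean()),
    "clustering": lambda W: float(clustering_coefficient(W).mean()),
    "local_efficiency": lambda W: float(local_efficiency(W).mean()),
    "density": network_density,
}


# ---------------------------------------------------------------------------
# Threshold curves and AUC
# ---------------------------------------------------------------------------


@dataclass
class MetricCurve:
    """One measure evaluated across the sparsity grid, with its AUC."""

    metric: str
    thresholds: np.ndarray
    values: np.ndarray
    auc: float


def metric_curve(network, metric: str, config: AnalysisConfig | None = None) -> MetricCurve:
    """Evaluate a named measure at every sparsity threshold and integrate
    the curve by the trapezoidal rule."""
    config = config or AnalysisConfig()
    grid = config.sparsity_grid
    if grid.size < 2:
        raise ValueError("AUC needs at least two thresholds")
    fn = NETWORK_MEASURES[metric]
    W = _as_matrix(network)
    values = np.array([fn(threshold_by_sparsity(W, s)) for s in grid])
    auc = float(np.trapezoid(values, grid))
    if not np.isfinite(auc):
        raise ValueError("non-finite AUC")
    return MetricCurve(metric, grid, values, auc)


def metric_auc(
    cohort: Cohort | list[Connectome],
    metric: str,
    config: AnalysisConfig | None = None,
) -> np.ndarray:
    """Per-subject AUC of a measure over the sparsity grid."""
    subjects = getattr(cohort, "connectomes", cohort)
    return np.array([metric_curve(c, metric, config).auc for c in subjects])


def cohort_auc_table(
    cohort: Cohort,
    metrics: list[str] | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Tidy per-subject AUC table for a cohort (one column per measure)."""
    metrics = metrics or list(NETWORK_MEASURES)
    data = {m: metric_auc(cohort, m, config) for m in metrics}
    df = pd.DataFrame(data)
    df.insert(0, "subject_id", [c.subject_id for c in cohort.connectomes])
    df.insert(1, "condition", cohort.condition)
    return df


# ---------------------------------------------------------------------------
# Group comparison of AUCs
# ---------------------------------------------------------------------------


def _f_test_var(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va >= vb:
        f, dfn, dfd = (va / vb if vb > 0 else np.inf), len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = 2 * stats.f.sf(f, dfn, dfd)
    return float(min(p, 1.0))


def compare_groups_auc(
    group_a: dict[str, np.ndarray],
    group_b: dict[str, np.ndarray],
    alpha: float = 0.05,
    labels: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Per-measure two-sample comparison with Holm-Sidak correction.

    For each measure: D'Agostino-Pearson omnibus normality on both groups;
    if both pass (p > alpha), an unpaired two-tailed t test (Welch when an
    F test finds unequal variances at alpha), otherwise a Mann-Whitney U
    test. Raw p-values are Holm-Sidak adjusted across the measure family.
    """
    if set(group_a) != set(group_b):
        raise ValueError("groups must share the same measure families")
    rows = []
    for measure in group_a:
        a = np.asarray(group_a[measure], dtype=float)
        b = np.asarray(group_b[measure], dtype=float)
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            rows.append((measure, "degenerate", 1.0, np.nan, np.nan, np.nan))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_norm_a = stats.normaltest(a).pvalue if len(a) >= 8 else np.nan
            p_norm_b = stats.normaltest(b).pvalue if len(b) >= 8 else np.nan
        normal = (np.isnan(p_norm_a) or p_norm_a > alpha) and (
            np.isnan(p_norm_b) or p_norm_b > alpha
        )
        p_var = _f_test_var(a, b)
        if normal:
            equal_var = p_var >= alpha
            test = "t" if equal_var else "welch_t"
            p_raw = stats.ttest_ind(a, b, equal_var=equal_var).pvalue
        else:
            test = "mannwhitney"
            p_raw = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        rows.append((measure, test, float(p_raw), p_norm_a, p_norm_b, p_var))
    df = pd.DataFrame(
        rows,
        columns=["measure", "test", "p_raw", "p_normal_a", "p_normal_b", "p_var"],
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # p == 1 edge case
        reject, p_adj, *_ = multipletests(
            df["p_raw"], alpha=alpha, method="holm-sidak"
        )
    df["p_adjusted"] = p_adj
    df["significant"] = reject
    df.insert(1, "group_a", labels[0])
    df.insert(2, "group_b", labels[1])
    return df
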