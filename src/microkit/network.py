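"""Compositionally-aware co-abundance networks and topology comparison.

SparCC estimates correlations between *basis* (absolute) abundances from
compositional count data via log-ratio variances; here the full published
procedure is implemented: Dirichlet-posterior resampling of fractions,
the approximate basis-variance linear solve, iterative exclusion of the
strongest pairs, and a median over estimation iterations. Edges are kept at
strict thresholds (default P < 0.05 and |R| > 0.7) after a prevalence
filter, and topology metrics follow the Cytoscape NetworkAnalyzer
conventions (low-degree nodes count as 0 in the mean clustering coefficient;
disconnected pairs are ignored by the characteristic path length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import OtuTable

__all__ = [
    "CorrelationNetwork",
    "TopologySummary",
    "prevalence_filter",
    "sparcc",
    "permutation_pvalues",
    "build_network",
    "topology",
    "compare_topologies",
]


@dataclass
class CorrelationNetwork:
    """Thresholded correlation graph: nodes, signed edges, and thresholds."""

    nodes: list[str]
    edges: list[tuple[str, str, float, float]]  # (i, j, R, p), unordered pairs
    prevalence_min: float | None = None
    p_max: float | None = None
    r_min_abs: float | None = None
    n_permutations: int | None = None

    def __post_init__(self) -> None:
        seen = set()
        for i, j, r, p in self.edges:
            if i == j:
                raise ValueError(f"self-edge on {i}")
            key = frozenset((i, j))
            if key in seen:
                raise ValueError(f"duplicate edge {i}-{j}")
            seen.add(key)
            if self.p_max is not None and not p < self.p_max:
                raise ValueError(f"edge {i}-{j} violates p < {self.p_max}")
            if self.r_min_abs is not None and not abs(r) > self.r_min_abs:
                raise ValueError(f"edge {i}-{j} violates |R| > {self.r_min_abs}")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for i, j, r, p in self.edges:
            g.add_edge(i, j, R=float(r), p=float(p))
        return g


@dataclass
class TopologySummary:
    """Scalar graph metrics plus per-node degree/centrality vectors."""

    n_nodes: int
    n_edges: int
    n_isolated: int
    n_components: int
    characteristic_path_length: float
    clustering_coefficient: float
    network_centralization: float
    avg_num_neighbors: float
    network_density: float
    degree: pd.Series = field(repr=False)
    eigenvector_centrality: pd.Series = field(repr=False)

    def scalars(self) -> dict[str, float]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_isolated": self.n_isolated,
            "n_components": self.n_components,
            "characteristic_path_length": self.characteristic_path_length,
            "clustering_coefficient": self.clustering_coefficient,
            "network_centralization": self.network_centralization,
            "avg_num_neighbors": self.avg_num_neighbors,
            "network_density": self.network_density,
        }


def prevalence_filter(table: OtuTable, min_fraction: float = 0.40) -> OtuTable:
    """Keep OTUs present (count > 0) in strictly more than ``min_fraction`` of samples."""
    frac = (table.counts > 0).mean(axis=0)
    keep = [o for o, f in zip(table.otu_ids, frac) if f > min_fraction]
    return table.select_otus(keep)


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _variation_matrix(log_fracs: np.ndarray) -> np.ndarray:
    """T_ij = var(log(x_i/x_j)) from per-sample log fractions (n x p)."""
    cov = np.cov(log_fracs, rowvar=False)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    np.fill_diagonal(t, 0.0)
    return t


def _basis_correlations(
    t: np.ndarray, n_exclusion_iter: int, exclusion_threshold: float
) -> np.ndarray:
    """One SparCC basis solve with iterative strongest-pair exclusion."""
    p = t.shape[0]
    m = np.ones((p, p)) + np.diag([p - 2.0] * p)
    excluded = np.zeros((p, p), dtype=bool)
    t_eff = t.copy()

    def solve():
        ti = t_eff.sum(axis=1)
        omega = np.linalg.solve(m, ti)
        omega = np.clip(omega, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        r = (omega[:, None] + omega[None, :] - t) / denom
        np.fill_diagonal(r, 1.0)
        return np.clip(r, -1.0, 1.0)

    r = solve()
    for _ in range(n_exclusion_iter):
        absr = np.abs(r.copy())
        np.fill_diagonal(absr, 0.0)
        absr[excluded] = 0.0
        i, j = np.unravel_index(np.argmax(absr), absr.shape)
        if absr[i, j] <= exclusion_threshold:
            break
        # dropping pair (i,j) from the linear system would make a component's
        # equation degenerate once its diagonal falls to 1
        if m[i, i] <= 2 or m[j, j] <= 2:
            break
        excluded[i, j] = excluded[j, i] = True
        m[i, i] -= 1.0
        m[j, j] -= 1.0
        m[i, j] -= 1.0
        m[j, i] -= 1.0
        t_eff[i, j] = 0.0
        t_eff[j, i] = 0.0
        r = solve()
    return r


def _sparcc_from_counts(
    counts: np.ndarray,
    rng: np.random.Generator,
    n_estimation_iter: int,
    n_exclusion_iter: int,
    exclusion_threshold: float,
) -> np.ndarray:
    n, p = counts.shape
    rs = np.empty((n_estimation_iter, p, p))
    for it in range(n_estimation_iter):
        # Dirichlet(counts + 1) posterior draw of component fractions per sample
        gamma = rng.standard_gamma(counts + 1.0)
        fracs = gamma / gamma.sum(axis=1, keepdims=True)
        t = _variation_matrix(np.log(fracs))
        rs[it] = _basis_correlations(t, n_exclusion_iter, exclusion_threshold)
    r = np.median(rs, axis=0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def sparcc(
    table: OtuTable,
    n_estimation_iter: int = 20,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """SparCC basis correlation matrix for an OTU count table.

    Per estimation iteration: draw fractions from the Dirichlet posterior
    (counts + 1), form the log-ratio variation matrix ``T_ij =
    var(log(x_i/x_j))``, solve the approximate basis-variance system, and
    derive ``r_ij = (w_i + w_j - T_ij) / (2 sqrt(w_i w_j))``; the strongest
    |r| pair above ``exclusion_threshold`` is iteratively removed from the
    system. The returned matrix is the elementwise median across iterations
    (symmetric, unit diagonal, clipped to [-1, 1]).
    """
    counts = np.asarray(table.counts, dtype=float)
    n, p = counts.shape
    if p < 4:
        raise ValueError(f"SparCC needs >= 4 OTUs, got {p}")
    if n < 4:
        raise ValueError(f"SparCC needs >= 4 samples, got {n}")
    if np.any(counts.sum(axis=1) <= 0):
        raise ValueError("samples with zero total counts")
    rng = np.random.default_rng(seed)
    r = _sparcc_from_counts(
        counts, rng, n_estimation_iter, n_exclusion_iter, exclusion_threshold
    )
    return pd.DataFrame(r, index=table.otu_ids, columns=table.otu_ids)


def permutation_pvalues(
    table: OtuTable,
    r_obs: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
    n_estimation_iter: int = 5,
    n_exclusion_iter: int = 10,
    exclusion_threshold: float = 0.1,
) -> pd.DataFrame:
    """Two-sided permutation p-values for SparCC correlations.

    Each permutation shuffles every OTU's counts across samples independently
    (destroying inter-OTU association, preserving marginals) and recomputes
    SparCC with a reduced number of estimation iterations (default 5).
    ``p_ij = (1 + #{|R_perm| >= |R_obs|}) / (n_perm + 1)``; the add-one keeps
    p strictly positive so the strict ``p < 0.05`` edge rule is meaningful.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    counts = np.asarray(table.counts, dtype=float)
    n, p = counts.shape
    obs = np.abs(r_obs.to_numpy())
    exceed = np.zeros((p, p))
    rng = np.random.default_rng(seed)
    for _ in range(n_perm):
        perm = np.empty_like(counts)
        for j in range(p):
            perm[:, j] = counts[rng.permutation(n), j]
        r_perm = _sparcc_from_counts(
            perm, rng, n_estimation_iter, n_exclusion_iter, exclusion_threshold
        )
        exceed += np.abs(r_perm) >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    np.fill_diagonal(pvals, 1.0)
    pvals = np.minimum(pvals, pvals.T)
    return pd.DataFrame(pvals, index=r_obs.index, columns=r_obs.columns)


def build_network(
    r: pd.DataFrame,
    p: pd.DataFrame,
    p_max: float = 0.05,
    r_min_abs: float = 0.7,
    prevalence_min: float | None = None,
    n_permutations: int | None = None,
) -> CorrelationNetwork:
    """Set an edge for every OTU pair with ``p < p_max`` and ``|R| > r_min_abs``.

    Both thresholds are strict; nodes failing every test stay in the node
    list as isolated nodes, and the sign of R is preserved on edges.
    """
    if list(r.index) != list(p.index) or list(r.columns) != list(p.columns):
        raise ValueError("R and p matrices are not aligned")
    ids = list(r.index)
    rv, pv = r.to_numpy(), p.to_numpy()
    edges = [
        (ids[i], ids[j], float(rv[i, j]), float(pv[i, j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if pv[i, j] < p_max and abs(rv[i, j]) > r_min_abs
    ]
    return CorrelationNetwork(
        nodes=ids,
        edges=edges,
        prevalence_min=prevalence_min,
        p_max=p_max,
        r_min_abs=r_min_abs,
        n_permutations=n_permutations,
    )


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

def _eigenvector_centrality(g: nx.Graph) -> pd.Series:
    """Principal adjacency eigenvector of the largest connected component,
    non-negative, max-normalised to 1; nodes outside that component get 0."""
    ec = pd.Series(0.0, index=list(g.nodes))
    comps = [sorted(c) for c in nx.connected_components(g)]
    if not comps:
        return ec
    comp = max(comps, key=lambda c: (len(c), c))
    if len(comp) == 1:
        ec[comp[0]] = 1.0
        return ec
    adj = nx.to_numpy_array(g, nodelist=comp, weight=None)
    eigvals, eigvecs = np.linalg.eigh(adj)
    v = eigvecs[:, -1]
    v = np.abs(v)  # Perron vector of a connected non-negative matrix
    v = v / v.max()
    for node, val in zip(comp, v):
        ec[node] = float(val)
    return ec


def topology(net: CorrelationNetwork, clustering_mode: str = "include_low_degree") -> TopologySummary:
    """Topology metrics of the unweighted, undirected edge set.

    ``characteristic_path_length`` averages shortest paths over connected
    pairs only; ``clustering_coefficient`` averages local clustering over all
    nodes, counting degree-<2 nodes as 0 (pass
    ``clustering_mode='exclude_low_degree'`` to average over degree->=2 nodes
    only); ``network_centralization`` is Freeman degree centralization
    ``sum(deg_max - deg_i) / ((n-1)(n-2))``.
    """
    if not net.nodes:
        raise ValueError("empty node set")
    g = net.to_graph()
    n = g.number_of_nodes()
    e = g.number_of_edges()
    degree = pd.Series({node: d for node, d in g.degree()}, dtype=float)[list(g.nodes)]
    n_isolated = int((degree == 0).sum())
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    avg_neighbors = 2.0 * e / n

    # mean shortest-path length over connected (unordered) pairs
    total_len, total_pairs = 0.0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total_len += sum(dists.values())
        total_pairs += k * (k - 1)
    cpl = total_len / total_pairs if total_pairs else 0.0

    local = nx.clustering(g)  # 0 for degree < 2
    if clustering_mode == "include_low_degree":
        cc = float(np.mean(list(local.values()))) if local else 0.0
    elif clustering_mode == "exclude_low_degree":
        vals = [v for node, v in local.items() if g.degree(node) >= 2]
        cc = float(np.mean(vals)) if vals else 0.0
    else:
        raise ValueError(f"unknown clustering_mode {clustering_mode!r}")

    if n > 2:
        centralization = float((degree.max() - degree).sum() / ((n - 1) * (n - 2)))
    else:
        centralization = 0.0

    return TopologySummary(
        n_nodes=n,
        n_edges=e,
        n_isolated=n_isolated,
        n_components=nx.number_connected_components(g),
        characteristic_path_length=cpl,
        clustering_coefficient=cc,
        network_centralization=centralization,
        avg_num_neighbors=avg_neighbors,
        network_density=density,
        degree=degree,
        eigenvector_centrality=_eigenvector_centrality(g),
    )


def compare_topologies(a: TopologySummary, b: TopologySummary) -> dict:
    """Two-sample KS tests on degree and eigenvector-centrality distributions,
    plus a side-by-side table of the scalar metrics."""
    report = {"scalars": pd.DataFrame({"a": a.scalars(), "b": b.scalars()})}
    for name, xa, xb in (
        ("degree", a.degree, b.degree),
        ("eigenvector_centrality", a.eigenvector_centrality, b.eigenvector_centrality),
    ):
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"{name}: need >= 2 values per network")
        ks = stats.ks_2samp(xa.to_numpy(), xb.to_numpy(), method="asymp")
        report[name] = {"ks_statistic": float(ks.statistic), "p_value": float(ks.pvalue)}
    return report
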