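"""SparCC compositional correlations and co-occurrence network extraction.

SparCC estimates correlations between the unobserved basis abundances
from compositional count data. For features i, j the log-ratio variance
t_ij = var(log(x_i/x_j)) satisfies

    t_ij = w_i + w_j - 2 r_ij sqrt(w_i w_j)

where w are basis variances. Under the sparsity assumption (correlations
average out), the basis variances solve a linear system in the t row
sums; strongly correlated pairs violate the assumption and are excluded
iteratively (strongest pair first) before re-solving.

The network layer thresholds |r|, keeps signed edges, and extracts the
seed-and-follow clusters: repeatedly take the most connected remaining
node and follow all positively correlated nodes; negative edges link
clusters, and nodes anticorrelated with a single cluster node are
trimmed as pendants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tables_io import FeatureTable

__all__ = [
    "sparcc_correlations",
    "build_network",
    "extract_clusters",
    "coexclusion_pairs",
    "CorrelationNetwork",
]


def _fractions_pseudocount(counts: np.ndarray) -> np.ndarray:
    k = counts.shape[1]
    c = counts + 1.0
    return c / c.sum(axis=1, keepdims=True)


def _basis_correlations(T: np.ndarray, exclusion_threshold: float, max_iter: int):
    """Solve the SparCC system, iteratively excluding strong pairs."""
    k = T.shape[0]
    included = ~np.eye(k, dtype=bool)

    def solve():
        d = included.sum(axis=1).astype(float)
        M = included.astype(float)
        M[np.diag_indices(k)] = d
        t_row = (T * included).sum(axis=1)
        w = np.linalg.lstsq(M, t_row, rcond=None)[0]
        w = np.maximum(w, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        r = (w[:, None] + w[None, :] - T) / denom
        np.fill_diagonal(r, 1.0)
        return r

    r = solve()
    for _ in range(max_iter):
        masked = np.where(included, np.abs(r), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        # never disconnect a feature from the system entirely
        if included[i].sum() <= 2 or included[j].sum() <= 2:
            break
        included[i, j] = included[j, i] = False
        r = solve()
    return r


def sparcc_correlations(
    table: FeatureTable,
    n_iterations: int = 10,
    exclusion_threshold: float = 0.1,
    n_inner: int = 1,
    seed: int | None = None,
) -> pd.DataFrame:
    """SparCC basis correlation matrix for the table's features.

    ``n_inner = 1`` uses a single pseudocount fraction estimate
    (c_i + 1)/(sum c + k); ``n_inner > 1`` averages (median) correlations
    over Dirichlet(c + 1) resamples of the fractions, the original
    algorithm's pseudo-replicate mode.
    """
    counts = table.counts.astype(float)
    n, k = counts.shape
    if k < 4:
        raise ValueError("SparCC needs at least 4 features")

    def corr_from_fracs(F):
        logF = np.log(F)
        # t_ij = var(log f_i) + var(log f_j) - 2 cov(log f_i, log f_j)
        C = np.cov(logF.T, ddof=1)
        v = np.diag(C)
        T = v[:, None] + v[None, :] - 2 * C
        return _basis_correlations(T, exclusion_threshold, n_iterations)

    if n_inner <= 1:
        r = corr_from_fracs(_fractions_pseudocount(counts))
    else:
        rng = np.random.default_rng(seed)
        draws = []
        alpha = counts + 1.0
        for _ in range(n_inner):
            gam = rng.gamma(alpha)
            F = gam / gam.sum(axis=1, keepdims=True)
            draws.append(corr_from_fracs(F))
        r = np.median(draws, axis=0)

    n_clamped = int((np.abs(r) > 1).sum())
    if n_clamped:
        warnings.warn(f"clamped {n_clamped} correlation entries to [-1, 1]")
    r = np.clip(r, -1.0, 1.0)
    r = (r + r.T) / 2.0
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=table.feature_ids, columns=table.feature_ids)


@dataclass
class CorrelationNetwork:
    """Thresholded signed correlation graph with extracted clusters."""

    graph: nx.Graph
    threshold: float
    clusters: list[set] = field(default_factory=list)
    seeds: list[str] = field(default_factory=list)
    pendants: list[tuple] = field(default_factory=list)  # (node, cluster_node, r)
    between_edges: list[tuple] = field(default_factory=list)  # (u, v, r)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u, v, d["r"], d["sign"]) for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["source", "target", "r", "sign"])


def build_network(correlations: pd.DataFrame, threshold: float = 0.3) -> CorrelationNetwork:
    """Keep edges with |r| >= threshold ("at least"); drop isolated nodes."""
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    r = correlations.to_numpy()
    ids = list(correlations.index)
    g = nx.Graph()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(r[i, j]) >= threshold:
                g.add_edge(
                    ids[i], ids[j], r=float(r[i, j]), sign=1 if r[i, j] > 0 else -1
                )
    return CorrelationNetwork(g, threshold)


def extract_clusters(network: CorrelationNetwork) -> CorrelationNetwork:
    """Seed-and-follow cluster extraction.

    Until no nodes remain: seed at the highest-degree remaining node
    (degree counts edges of both signs; ties break lexicographically),
    collect everything reachable from it through positive edges, and
    remove the cluster. Negative edges between clusters are recorded;
    a singleton whose only link is one negative edge into another
    cluster becomes a trimmed pendant.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    remaining = set(g.nodes)
    clusters: list[set] = []
    seeds: list[str] = []
    while remaining:
        # highest degree wins; ties break on lexicographically smallest id
        best_deg = max(g.degree(v) for v in remaining)
        seed = min(v for v in remaining if g.degree(v) == best_deg)
        cluster = {seed}
        frontier = [seed]
        while frontier:
            v = frontier.pop()
            for u in g.neighbors(v):
                if u in remaining and u not in cluster and g[v][u]["sign"] > 0:
                    cluster.add(u)
                    frontier.append(u)
        clusters.append(cluster)
        seeds.append(seed)
        remaining -= cluster

    membership = {v: ci for ci, cl in enumerate(clusters) for v in cl}
    between = [
        (u, v, g[u][v]["r"])
        for u, v in g.edges
        if membership[u] != membership[v]
    ]

    # pendants are flagged for trimming in display but stay in the cluster
    # partition, so clusters always cover the node set
    pendants = []
    for cl in clusters:
        if len(cl) != 1:
            continue
        (v,) = cl
        nbrs = list(g.neighbors(v))
        if len(nbrs) == 1 and g[v][nbrs[0]]["sign"] < 0:
            pendants.append((v, nbrs[0], g[v][nbrs[0]]["r"]))
    return CorrelationNetwork(
        g, network.threshold, clusters, seeds, pendants, between
    )


def _mismatches(seq_a: str, seq_b: str) -> int:
    if len(seq_a) != len(seq_b):
        return abs(len(seq_a) - len(seq_b)) + sum(
            x != y for x, y in zip(seq_a, seq_b)
        )
    return sum(x != y for x, y in zip(seq_a, seq_b))


def coexclusion_pairs(
    network: CorrelationNetwork,
    sequence_map: dict[str, str],
    max_mismatches: int = 1,
) -> pd.DataFrame:
    """Candidate niche-partitioned variant pairs.

    Node pairs linked negatively — directly, or sitting in two clusters
    joined by a negative edge — whose sequences differ by at most
    ``max_mismatches`` positions.
    """
    g = network.graph
    candidates = set()
    for u, v in g.edges:
        if g[u][v]["sign"] < 0:
            candidates.add(tuple(sorted((u, v))))
    membership = {v: ci for ci, cl in enumerate(network.clusters) for v in cl}
    linked_clusters = set()
    for u, v, _ in network.between_edges:
        if u in membership and v in membership:
            linked_clusters.add(tuple(sorted((membership[u], membership[v]))))
    for ci, cj in linked_clusters:
        for u in network.clusters[ci]:
            for v in network.clusters[cj]:
                candidates.add(tuple(sorted((u, v))))

    rows = []
    for u, v in sorted(candidates):
        if u not in sequence_map or v not in sequence_map:
            warnings.warn(f"no sequence for pair ({u}, {v}); skipped")
            continue
        mm = _mismatches(sequence_map[u].upper(), sequence_map[v].upper())
        if mm <= max_mismatches:
            r = g[u][v]["r"] if g.has_edge(u, v) else np.nan
            rows.append((u, v, mm, r))
    return pd.DataFrame(rows, columns=["node_a", "node_b", "mismatches", "r"])
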