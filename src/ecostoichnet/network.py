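"""Spearman co-occurrence networks and their topology.

Workflow: filter rare taxa (mean relative abundance and prevalence
thresholds), compute all pairwise Spearman rank correlations across the
samples in scope, keep only strong (|rho| > 0.9) and significant (p < 0.05)
pairs as undirected weighted edges, drop taxa left without any edge, then
summarise the graph with six topology metrics: node number, edge number,
average degree, average path length, average clustering coefficient and
modularity of a Louvain partition on |rho| weights.

With nine samples per stand the |rho| > 0.9 threshold sits near the
attainable extreme of the rank-correlation scale; the p-value defaults to
the two-sided t approximation, with an exact small-n permutation option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CorrelationNetwork, OTUTable


def filter_taxa(
    table: OTUTable,
    min_mean_relabund: float = 0.0001,
    min_prevalence: float = 0.5,
) -> OTUTable:
    """Keep taxa whose mean relative abundance and prevalence both pass.

    Relative abundance is computed per sample (count over column sum) before
    averaging; prevalence is the fraction of in-scope samples with a positive
    count. Thresholds are inclusive (>=).
    """
    if table.shape[1] < 2:
        raise ValueError("taxon filtering needs at least 2 samples")
    rel = table.relative_abundance()
    mean_rel = rel.mean(axis=1)
    prevalence = (table.counts > 0).mean(axis=1)
    keep = (mean_rel >= min_mean_relabund) & (prevalence >= min_prevalence)
    if not keep.any():
        raise ValueError(
            "all taxa removed by abundance/prevalence filter; relax "
            f"min_mean_relabund={min_mean_relabund} or min_prevalence={min_prevalence}"
        )
    return OTUTable(table.counts.loc[keep].copy(), table.kingdom)


def _permutation_spearman_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p from a permutation null of rho at sample size n.

    The null distribution is shared by every pair (it depends only on n for
    untied ranks), so it is simulated once — 20,000 random rank permutations
    under a fixed internal generator — and each |rho| is referred to it.
    Preferable to the t approximation when n is in the single digits.
    """
    rng = np.random.default_rng(12345)
    n_mc = 20000
    base = stats.zscore(np.arange(n, dtype=float))
    perms = np.array([rng.permutation(n) for _ in range(n_mc)], dtype=float)
    perms = stats.zscore(perms, axis=1)
    null_rho = perms @ base / n
    flat = np.abs(rho).ravel()
    p = (np.abs(null_rho)[None, :] >= flat[:, None] - 1e-12).mean(axis=1)
    return p.reshape(rho.shape)


def spearman_matrix(
    table: OTUTable, pvalue_method: Literal["t", "permutation"] = "t"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs Spearman rho and two-sided p over taxa (observations = samples).

    Ties receive average ranks. p follows the t approximation
    t = rho sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom; |rho| = 1 maps
    to p = 0. Zero-variance taxa yield NaN rho/p for their pairs, which can
    never become edges.
    """
    n_taxa, n = table.shape
    if n < 4:
        raise ValueError("Spearman correlation needs at least 4 samples")
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    X = table.counts.to_numpy(dtype=float)
    constant = X.std(axis=1) == 0
    good = np.flatnonzero(~constant)
    rho = np.full((n_taxa, n_taxa), np.nan)
    p_t = np.full((n_taxa, n_taxa), np.nan)
    if good.size >= 2:
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            r_sub, p_sub = stats.spearmanr(X[good].T)
        r_sub = np.atleast_2d(np.asarray(r_sub, dtype=float))
        p_sub = np.atleast_2d(np.asarray(p_sub, dtype=float))
        if r_sub.shape == (1, 1):  # scipy collapses the 2-variable case
            r_sub = np.array([[1.0, r_sub[0, 0]], [r_sub[0, 0], 1.0]])
            p_sub = np.array([[0.0, p_sub[0, 0]], [p_sub[0, 0], 0.0]])
        rho[np.ix_(good, good)] = r_sub
        p_t[np.ix_(good, good)] = p_sub
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    if pvalue_method == "t":
        p = p_t
        with np.errstate(invalid="ignore"):
            p[np.isclose(np.abs(rho), 1.0)] = 0.0
    elif pvalue_method == "permutation":
        p = _permutation_spearman_pvalues(rho, n)
    else:
        raise ValueError(f"unknown pvalue_method {pvalue_method!r}")
    p[np.isnan(rho)] = np.nan
    np.fill_diagonal(p, np.where(constant, np.nan, 0.0))
    idx = table.counts.index
    return pd.DataFrame(rho, index=idx, columns=idx), pd.DataFrame(
        p, index=idx, columns=idx
    )


def build_network(
    rho: pd.DataFrame,
    p: pd.DataFrame,
    r_min: float = 0.9,
    alpha: float = 0.05,
    sample_ids: list[str] | None = None,
    bh_correct: bool = False,
) -> CorrelationNetwork:
    """Threshold the correlation matrices into an undirected weighted network.

    Edge (i, j) exists iff |rho_ij| > r_min (strict) and p_ij < alpha. Taxa
    left with degree zero are dropped from the node set. Optional
    Benjamini-Hochberg correction is applied to the upper-triangle p-values
    before thresholding.
    """
    if not (0 < r_min <= 1):
        raise ValueError(f"r_min must be in (0, 1], got {r_min}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if rho.shape != p.shape or not rho.index.equals(p.index):
        raise ValueError("rho and p matrices must be conformable")
    taxa = list(rho.index)
    r = rho.to_numpy()
    pv = p.to_numpy().copy()
    iu = np.triu_indices(len(taxa), k=1)
    if bh_correct:
        flat = pv[iu]
        ok = ~np.isnan(flat)
        adj = np.full_like(flat, np.nan)
        if ok.any():
            adj[ok] = stats.false_discovery_control(flat[ok], method="bh")
        pv[iu] = adj
        pv.T[iu] = adj
    g = nx.Graph()
    for a, b in zip(*iu):
        rv, pval = r[a, b], pv[a, b]
        if np.isnan(rv) or np.isnan(pval):
            continue
        if abs(rv) > r_min and pval < alpha:
            g.add_edge(taxa[a], taxa[b], rho=float(rv), sign=1 if rv > 0 else -1)
    return CorrelationNetwork(
        g, r_min=r_min, alpha=alpha, sample_ids=list(sample_ids or [])
    )


@dataclass(frozen=True)
class TopologyMetrics:
    node_number: int
    edge_number: int
    average_degree: float
    average_path_length: float
    average_clustering_coefficient: float
    modularity: float

    def as_row(self) -> dict:
        return vars(self).copy()


def detect_communities(
    net: CorrelationNetwork, seed: int = 0, method: Literal["louvain", "greedy"] = "louvain"
) -> list[set]:
    """Partition the network's nodes into communities on |rho| edge weights."""
    if net.edge_number == 0:
        raise ValueError("community detection needs at least one edge")
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, weight=abs(d["rho"]))
    if method == "louvain":
        comms = nx.community.louvain_communities(g, weight="weight", seed=seed)
    elif method == "greedy":
        comms = nx.community.greedy_modularity_communities(g, weight="weight")
    else:
        raise ValueError(f"unknown community method {method!r}")
    return [set(c) for c in comms]


def modularity(net: CorrelationNetwork, partition: list[set]) -> float:
    """Newman weighted modularity of a partition on |rho| edge weights."""
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes)
    for u, v, d in net.graph.edges(data=True):
        g.add_edge(u, v, weight=abs(d["rho"]))
    return float(nx.community.modularity(g, partition, weight="weight"))


def average_path_length(graph: nx.Graph) -> float:
    """Mean shortest-path length (unweighted hops) over reachable ordered pairs.

    Disconnected pairs are excluded, the igraph-style convention for
    fragmented graphs.
    """
    total, pairs = 0, 0
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        k = len(comp)
        if k < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += k - 1
    if pairs == 0:
        return 0.0
    return total / pairs


def topology(net: CorrelationNetwork, seed: int = 0) -> TopologyMetrics:
    """The six topology metrics of a co-occurrence network.

    Clustering is the unweighted local clustering coefficient averaged over
    all nodes (degree < 2 contributes 0); modularity is the weighted
    modularity of the seeded Louvain partition.
    """
    n = net.node_number
    if n == 0:
        raise ValueError("topology undefined for an empty network")
    e = net.edge_number
    avg_degree = 2 * e / n
    if e == 0:
        raise ValueError("modularity undefined for an edgeless network")
    apl = average_path_length(net.graph)
    clustering = float(nx.average_clustering(net.graph))
    part = detect_communities(net, seed=seed)
    mod = modularity(net, part)
    return TopologyMetrics(
        node_number=n,
        edge_number=e,
        average_degree=avg_degree,
        average_path_length=apl,
        average_clustering_coefficient=clustering,
        modularity=mod,
    )


def topology_table(nets: dict[str, CorrelationNetwork], seed: int = 0) -> pd.DataFrame:
    """One topology row per network, in the canonical column order."""
    rows = {name: topology(net, seed=seed).as_row() for name, net in nets.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "network"
    return out[
        [
            "node_number",
            "edge_number",
            "average_degree",
            "average_path_length",
            "average_clustering_coefficient",
            "modularity",
        ]
    ]
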