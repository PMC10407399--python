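"""Rank-average consensus network, hub extraction and Markov clustering.

Edges from the individual inference methods are combined by averaging their
fractional ranks (unlisted candidate pairs receive the mid-rank of the
unoccupied positions), the strongest K interactions are kept, the top degree
fraction defines the hub genes, and MCL partitions the network into
subnetworks from which regulator-target clusters are read off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from tcellgrn.grn import RankedEdgeList

__all__ = [
    "ConsensusNetwork",
    "average_rank_consensus",
    "top_k",
    "hubs",
    "mcl",
    "subnetwork_of",
]


@dataclass
class ConsensusNetwork:
    """Undirected consensus edges; lower mean rank = stronger interaction."""

    edges: pd.DataFrame   # gene_a, gene_b, score (mean rank), n_methods
    nodes: list[str]

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) and (e["gene_a"] == e["gene_b"]).any():
            raise ValueError("self-edges are not allowed")

    @property
    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=pd.Index(self.nodes, name="gene"), dtype=int)
        for col in ("gene_a", "gene_b"):
            counts = self.edges[col].value_counts()
            deg = deg.add(counts, fill_value=0)
        return deg.astype(int)

    def __len__(self) -> int:
        return len(self.edges)


def _symmetrized_ranks(edge_list: RankedEdgeList) -> pd.DataFrame:
    """Collapse a directed list to undirected max-weight edges and re-rank."""
    e = edge_list.edges
    if not len(e):
        return pd.DataFrame(columns=["gene_a", "gene_b", "rank"])
    if edge_list.directed:
        a = e[["gene_a", "gene_b", "score"]].copy()
        key = np.where(a["gene_a"] < a["gene_b"],
                       a["gene_a"] + "\t" + a["gene_b"],
                       a["gene_b"] + "\t" + a["gene_a"])
        a["pair"] = key
        best = a.groupby("pair", sort=False)["score"].max().reset_index()
        best[["gene_a", "gene_b"]] = best["pair"].str.split("\t", expand=True)
        best["rank"] = stats.rankdata(-best["score"].to_numpy(), method="average")
        return best[["gene_a", "gene_b", "rank"]]
    return e[["gene_a", "gene_b", "rank"]].copy()


def average_rank_consensus(edge_lists: list[RankedEdgeList], universe) -> ConsensusNetwork:
    """Mean fractional rank per candidate pair across methods.

    Every unordered pair of ``universe`` genes is a candidate.  Per method,
    listed edges keep their fractional ranks; unlisted candidates receive the
    mid-rank of the unoccupied positions, (L + 1 + E) / 2 with L the list
    length and E the number of candidate pairs.  Directed lists are
    symmetrized by max weight before ranking.
    """
    if len(edge_lists) < 1:
        raise ValueError("at least one edge list required")
    nodes = sorted(set(universe))
    node_set = set(nodes)
    for el in edge_lists:
        listed = set(el.edges["gene_a"]) | set(el.edges["gene_b"])
        if listed and not (listed & node_set):
            raise ValueError(f"edge list {el.method!r} shares no genes with the universe")
    pairs = list(combinations(nodes, 2))
    E = len(pairs)
    index = {p: i for i, p in enumerate(pairs)}
    total = np.zeros(E)
    n_listed = np.zeros(E, dtype=int)
    for el in edge_lists:
        ranks = np.full(E, np.nan)
        sym = _symmetrized_ranks(el)
        for a, b, r in sym.itertuples(index=False):
            key = (a, b) if a < b else (b, a)
            if key in index:
                ranks[index[key]] = r
        listed = np.isfinite(ranks)
        L = int(listed.sum())
        default = (L + 1 + E) / 2.0
        n_listed += listed
        total += np.where(listed, ranks, default)
    score = total / len(edge_lists)
    edges = pd.DataFrame({
        "gene_a": [p[0] for p in pairs],
        "gene_b": [p[1] for p in pairs],
        "score": score,
        "n_methods": n_listed,
    }).sort_values(["score", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)
    return ConsensusNetwork(edges=edges, nodes=nodes)


def top_k(consensus: ConsensusNetwork, k: int = 10_000) -> ConsensusNetwork:
    """Keep the k strongest (smallest mean-rank) consensus interactions.

    Boundary ties are broken by (gene_a, gene_b) lexicographic order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    edges = consensus.edges.sort_values(
        ["score", "gene_a", "gene_b"], kind="stable").iloc[:k].reset_index(drop=True)
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    return ConsensusNetwork(edges=edges, nodes=nodes)


def hubs(consensus: ConsensusNetwork, fraction: float = 0.20) -> tuple[list[str], int]:
    """The top degree fraction of nodes and the edge count they participate in.

    Degree is plain (unweighted) connectivity; ties break by gene id.  Returns
    ceil(fraction x n_nodes) hub genes and the number of network edges with at
    least one hub endpoint.
    """
    if not len(consensus.edges):
        raise ValueError("empty network")
    deg = consensus.degrees
    n_hubs = math.ceil(fraction * len(consensus.nodes))
    ordered = sorted(consensus.nodes, key=lambda g: (-deg[g], g))
    hub_genes = ordered[:n_hubs]
    hub_set = set(hub_genes)
    n_edges = int((consensus.edges["gene_a"].isin(hub_set)
                   | consensus.edges["gene_b"].isin(hub_set)).sum())
    return hub_genes, n_edges


def mcl(network: ConsensusNetwork | pd.DataFrame, inflation: float = 2.0,
        expansion: int = 2, max_iter: int = 100, tol: float = 1e-6,
        prune: float = 1e-8) -> dict[str, int]:
    """Markov clustering of an undirected network.

    Self-loops (weight = the node's maximum incident weight) are added, the
    adjacency is column-normalized, and expansion (matrix power) alternates
    with inflation (elementwise power + renormalization) and pruning until the
    matrix stops changing.  Clusters are the weakly connected components of the
    attractor support; every node lands in exactly one cluster.
    """
    edges = network.edges if isinstance(network, ConsensusNetwork) else network
    if not len(edges):
        raise ValueError("mcl requires at least one edge")
    nodes = sorted(set(edges["gene_a"]) | set(edges["gene_b"]))
    idx = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    weight_col = edges["weight"] if "weight" in edges.columns else pd.Series(1.0, index=edges.index)
    for (a, b), w in zip(edges[["gene_a", "gene_b"]].itertuples(index=False), weight_col):
        W[idx[a], idx[b]] = W[idx[b], idx[a]] = float(w)
    np.fill_diagonal(W, W.max(axis=1))
    M = W / W.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = M
        M = np.linalg.matrix_power(M, expansion)
        M = M**inflation
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.max(np.abs(M - prev)) < tol:
            converged = True
            break
    if not converged:
        warnings.warn("mcl: no convergence within max_iter; returning current clustering")
    support = nx.Graph()
    support.add_nodes_from(range(n))
    support.add_edges_from(zip(*np.nonzero(M > prune)))
    clusters: dict[str, int] = {}
    for cid, comp in enumerate(nx.connected_components(support), start=1):
        for i in comp:
            clusters[nodes[i]] = cid
    return clusters


def subnetwork_of(clusters: dict[str, int], gene: str) -> set[str]:
    """The member set of the cluster containing ``gene``."""
    if gene not in clusters:
        raise KeyError(f"gene {gene!r} is not clustered")
    cid = clusters[gene]
    return {g for g, c in clusters.items() if c == cid}
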