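"""Recovery metrics against the planted ground truth."""

from __future__ import annotations

from itertools import combinations

import numpy as np
from sklearn.metrics import average_precision_score

from tcellgrn.consensus import ConsensusNetwork, _symmetrized_ranks
from tcellgrn.grn import RankedEdgeList

__all__ = ["edge_recovery_aupr", "random_baseline_aupr"]


def _undirected(pairs) -> set[tuple[str, str]]:
    return {tuple(sorted(p)) for p in pairs}


def edge_recovery_aupr(result: RankedEdgeList | ConsensusNetwork,
                       truth_pairs, universe) -> float:
    """Area under precision-recall of an edge ranking against planted edges.

    Scores span every unordered candidate pair of ``universe``; pairs a method
    did not list receive the mid-rank of the unlisted positions, so partial
    lists are comparable with full ones.  Higher score = stronger edge.
    """
    nodes = sorted(set(universe))
    pairs = list(combinations(nodes, 2))
    E = len(pairs)
    index = {p: i for i, p in enumerate(pairs)}
    if isinstance(result, ConsensusNetwork):
        scores = np.full(E, np.nan)
        for a, b, s in result.edges[["gene_a", "gene_b", "score"]].itertuples(index=False):
            key = (a, b) if a < b else (b, a)
            if key in index:
                scores[index[key]] = -s  # lower mean rank = stronger
        default = -(np.nanmax(-scores) if np.isfinite(scores).any() else 0.0) - 1.0
        scores = np.where(np.isfinite(scores), scores, default)
    else:
        ranks = np.full(E, np.nan)
        for a, b, r in _symmetrized_ranks(result).itertuples(index=False):
            key = (a, b) if a < b else (b, a)
            if key in index:
                ranks[index[key]] = r
        L = int(np.isfinite(ranks).sum())
        ranks = np.where(np.isfinite(ranks), ranks, (L + 1 + E) / 2.0)
        scores = -ranks
    truth = _undirected(truth_pairs)
    labels = np.array([p in truth for p in pairs])
    if not labels.any():
        raise ValueError("no truth edge lies inside the universe")
    return float(average_precision_score(labels, scores))


def random_baseline_aupr(truth_pairs, universe) -> float:
    """Prevalence of true edges among candidate pairs (the chance-level AUPR)."""
    nodes = sorted(set(universe))
    E = len(nodes) * (len(nodes) - 1) // 2
    truth = {p for p in _undirected(truth_pairs) if p[0] in set(nodes) and p[1] in set(nodes)}
    return len(truth) / E
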