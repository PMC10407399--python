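"""Gene-regulatory-network inference engines.

Five complementary edge-scoring methods, each emitting a :class:`RankedEdgeList`:

* ``pearson_network`` — thresholded absolute Pearson correlation;
* ``aracne`` — mutual information with a chi-square significance gate and the
  data-processing-inequality pruning of likely-indirect edges;
* ``tinge_like`` — the same mutual information, unfiltered (every pair ranked);
* ``clr`` — MI z-scored against each gene's background MI distribution
  (context likelihood of relatedness);
* ``genie3_like`` — tree-ensemble importance of regulators for each target
  (directed).

Mutual information uses a rank-transform + equal-width binning plug-in
estimator in bits, which is exactly invariant under strictly monotone
per-gene transforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from tcellgrn.io_preprocess import ExpressionMatrix

__all__ = [
    "RankedEdgeList",
    "MIEstimate",
    "mi_matrix",
    "mi_significance",
    "aracne",
    "tinge_like",
    "clr",
    "genie3_like",
    "pearson_network",
]


@dataclass
class RankedEdgeList:
    """Scored gene-gene (or TF->target) interactions from one method.

    ``edges`` columns: gene_a, gene_b, score, rank (fractional, 1 = strongest,
    ties averaged).  Undirected edges are stored with gene_a < gene_b;
    ``directed`` marks TF->target semantics (gene_a regulates gene_b).
    ``universe`` is the number of candidate pairs the method considered.
    """

    method: str
    edges: pd.DataFrame
    universe: int
    directed: bool = False

    def __post_init__(self) -> None:
        e = self.edges
        if len(e):
            if not np.all(np.isfinite(e["score"])):
                raise ValueError("edge scores must be finite")
            if (e["gene_a"] == e["gene_b"]).any():
                raise ValueError("self-edges are not allowed")
            expected = stats.rankdata(-e["score"].to_numpy(), method="average")
            if not np.allclose(np.sort(e["rank"]), np.sort(expected)):
                raise ValueError("ranks are not a permutation-with-ties of 1..L")

    def __len__(self) -> int:
        return len(self.edges)


def _finalize(method: str, rows: list[dict], universe: int,
              directed: bool = False, top_k: int | None = None) -> RankedEdgeList:
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "score"])
    if len(edges):
        edges["rank"] = stats.rankdata(-edges["score"].to_numpy(), method="average")
        edges = edges.sort_values(["rank", "gene_a", "gene_b"], kind="stable").reset_index(drop=True)
        if top_k is not None and len(edges) > top_k:
            edges = edges.iloc[:top_k].copy()
            edges["rank"] = stats.rankdata(-edges["score"].to_numpy(), method="average")
    else:
        edges["rank"] = pd.Series(dtype=float)
    return RankedEdgeList(method=method, edges=edges, universe=universe, directed=directed)


@dataclass
class MIEstimate:
    """Pairwise mutual information (bits) with the discretization that made it."""

    mi: pd.DataFrame
    bins: int
    labels: np.ndarray        # genes x samples integer bin labels
    n_samples: int

    @property
    def genes(self) -> list[str]:
        return list(self.mi.index)


def _bin_labels(values: np.ndarray, bins: int) -> np.ndarray:
    """Rank-transform each row then equal-width bin the ranks (equal frequency)."""
    n = values.shape[1]
    out = np.empty_like(values, dtype=np.int64)
    for i, row in enumerate(values):
        ranks = stats.rankdata(row, method="average")
        out[i] = np.minimum(((ranks - 0.5) / n * bins).astype(np.int64), bins - 1)
    return out


def mi_matrix(matrix: ExpressionMatrix, bins: int | None = None, seed: int = 0) -> MIEstimate:
    """Plug-in mutual information over all gene pairs.

    Each gene is rank-transformed and binned into B equal-width rank bins
    (default B = clamp(round(n^(1/3)), 3, 16)); MI_ij = sum p log2(p/(px py))
    over occupied joint cells.  The diagonal carries the marginal entropy
    H(i) = MI(i, i).  Constant genes have zero MI against everything.
    """
    values = matrix.values.to_numpy(float)
    n_genes, n = values.shape
    if n < 8:
        raise ValueError("mi_matrix needs at least 8 samples")
    B = bins if bins is not None else int(np.clip(round(n ** (1 / 3)), 3, 16))
    if (values.std(axis=1) == 0).any():
        warnings.warn("mi_matrix: constant gene(s) have zero MI against everything")
    labels = _bin_labels(values, B)
    mi = np.zeros((n_genes, n_genes))
    marg = np.stack([np.bincount(labels[i], minlength=B) for i in range(n_genes)]) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.nansum(np.where(marg > 0, marg * np.log2(marg), 0.0), axis=1)
    for i in range(n_genes):
        li = labels[i]
        for j in range(i + 1, n_genes):
            joint = np.bincount(li * B + labels[j], minlength=B * B).reshape(B, B) / n
            outer = np.outer(marg[i], marg[j])
            occ = joint > 0
            mi[i, j] = mi[j, i] = float(np.sum(joint[occ] * np.log2(joint[occ] / outer[occ])))
    np.fill_diagonal(mi, ent)
    mi = np.maximum(mi, 0.0)
    frame = pd.DataFrame(mi, index=matrix.genes, columns=matrix.genes)
    return MIEstimate(mi=frame, bins=B, labels=labels, n_samples=n)


def mi_significance(estimate: MIEstimate, method: str = "chi2",
                    n_perm: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Independence p-value per gene pair.

    ``chi2``: the G-statistic 2 n ln2 MI is chi-square with (B-1)^2 degrees of
    freedom under independence.  ``permutation``: one margin of each pair is
    permuted and p = (1 + #{MI* >= MI}) / (n_perm + 1).
    """
    mi = estimate.mi.to_numpy(float)
    n, B = estimate.n_samples, estimate.bins
    genes = estimate.genes
    if method == "chi2":
        G = 2.0 * n * np.log(2.0) * mi
        p = stats.chi2.sf(G, (B - 1) ** 2)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        labels = estimate.labels
        p = np.ones_like(mi)
        marg = np.stack([np.bincount(labels[i], minlength=B) for i in range(len(genes))]) / n
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                null = np.empty(n_perm)
                lj = labels[j]
                for t in range(n_perm):
                    perm = rng.permutation(lj)
                    joint = np.bincount(labels[i] * B + perm, minlength=B * B).reshape(B, B) / n
                    outer = np.outer(marg[i], marg[j])
                    occ = joint > 0
                    null[t] = np.sum(joint[occ] * np.log2(joint[occ] / outer[occ]))
                p[i, j] = p[j, i] = (1 + int((null >= mi[i, j]).sum())) / (n_perm + 1)
    else:
        raise ValueError(f"unknown method {method!r}")
    np.fill_diagonal(p, np.nan)
    return pd.DataFrame(p, index=genes, columns=genes)


def aracne(estimate: MIEstimate, p_matrix: pd.DataFrame, p_threshold: float = 0.05,
           dpi_tolerance: float = 0.01) -> RankedEdgeList:
    """MI network with significance gate and data-processing-inequality pruning.

    Edges with p < ``p_threshold`` survive the gate; then for every triangle
    the weakest edge is removed when its MI falls below (1 - tolerance) times
    the smaller of the other two — removals are decided against the gated graph
    and applied simultaneously, so the result is order-independent.
    """
    mi = estimate.mi.to_numpy(float).copy()
    np.fill_diagonal(mi, 0.0)
    genes = estimate.genes
    surviving = p_matrix.to_numpy(float) < p_threshold
    np.fill_diagonal(surviving, False)
    factor = 1.0 - dpi_tolerance
    remove = np.zeros_like(surviving)
    for k in range(len(genes)):
        via_k = np.outer(surviving[:, k], surviving[:, k])
        bound = np.minimum.outer(mi[:, k], mi[:, k]) * factor
        remove |= surviving & via_k & (mi < bound)
    keep = surviving & ~remove
    rows = [
        {"gene_a": genes[i], "gene_b": genes[j], "score": mi[i, j]}
        for i in range(len(genes)) for j in range(i + 1, len(genes)) if keep[i, j]
    ]
    return _finalize("aracne", rows, universe=len(genes) * (len(genes) - 1) // 2)


def tinge_like(estimate: MIEstimate) -> RankedEdgeList:
    """Every gene pair ranked by MI, no significance or DPI filtering."""
    mi = estimate.mi.to_numpy(float)
    genes = estimate.genes
    rows = [
        {"gene_a": genes[i], "gene_b": genes[j], "score": mi[i, j]}
        for i in range(len(genes)) for j in range(i + 1, len(genes))
    ]
    return _finalize("tinge", rows, universe=len(rows))


def clr(estimate: MIEstimate, top_k: int | None = None) -> RankedEdgeList:
    """Context likelihood of relatedness.

    Each MI value is z-scored against its row's background (mean/sd over the
    row excluding the diagonal, negatives clipped at 0) and the pair score is
    sqrt(z_i(j)^2 + z_j(i)^2).
    """
    mi = estimate.mi.to_numpy(float).copy()
    np.fill_diagonal(mi, np.nan)
    mu = np.nanmean(mi, axis=1)
    sd = np.nanstd(mi, axis=1)
    if (sd == 0).any():
        warnings.warn("clr: zero-variance MI row(s); their z contribution is 0")
    genes = estimate.genes
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mi - mu[:, None]) / sd[:, None]
    z = np.where(np.isfinite(z), np.maximum(z, 0.0), 0.0)
    score = np.sqrt(z**2 + z.T**2)
    rows = [
        {"gene_a": genes[i], "gene_b": genes[j], "score": score[i, j]}
        for i in range(len(genes)) for j in range(i + 1, len(genes))
    ]
    return _finalize("clr", rows, universe=len(rows), top_k=top_k)


def genie3_like(matrix: ExpressionMatrix, regulators, n_trees: int = 1000,
                seed: int = 0, top_k: int | None = None) -> RankedEdgeList:
    """Tree-ensemble regulator importance, one bagged forest per target.

    For each target gene a random forest (sqrt(#regulators) candidate splits
    per node) predicts the target from all other regulators; the edge weight is
    the regulator's share of the total impurity reduction, so weights sum to 1
    per target.  Directed: gene_a regulates gene_b.
    """
    regulators = [r for r in regulators if r in matrix.values.index]
    values = matrix.values
    rows: list[dict] = []
    n_targets = 0
    for t_idx, target in enumerate(matrix.genes):
        preds = [r for r in regulators if r != target]
        if len(preds) < 2:
            warnings.warn(f"genie3_like: target {target!r} skipped (<2 regulators)")
            continue
        X = values.loc[preds].to_numpy(float).T
        y = values.loc[target].to_numpy(float)
        rf = RandomForestRegressor(
            n_estimators=n_trees, max_features="sqrt",
            random_state=(seed * 1_000_003 + t_idx) % (2**31), n_jobs=1,
        )
        rf.fit(X, y)
        importances = rf.feature_importances_
        n_targets += 1
        for reg, w in zip(preds, importances):
            if w > 0:
                rows.append({"gene_a": reg, "gene_b": target, "score": float(w)})
    universe = n_targets * max(len(regulators) - 1, 0)
    return _finalize("genie3", rows, universe=universe, directed=True, top_k=top_k)


def pearson_network(matrix: ExpressionMatrix, cutoff: float = 0.7) -> RankedEdgeList:
    """All gene pairs with |Pearson r| >= cutoff, ranked by |r| descending."""
    values = matrix.values.to_numpy(float)
    if values.shape[1] < 3:
        raise ValueError("pearson_network needs at least 3 samples")
    genes = matrix.genes
    sd = values.std(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    corr = np.where(np.isfinite(corr), corr, 0.0)
    rows = [
        {"gene_a": genes[i], "gene_b": genes[j], "score": abs(corr[i, j])}
        for i in range(len(genes)) for j in range(i + 1, len(genes))
        if abs(corr[i, j]) >= cutoff and sd[i] > 0 and sd[j] > 0
    ]
    return _finalize("pearson", rows, universe=len(genes) * (len(genes) - 1) // 2)
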