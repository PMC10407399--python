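"""Co-expression analyses: SOM, topological-overlap modules, eigengenes, GSEA.

Module detection follows the weighted co-expression recipe: soft-thresholded
adjacency a_ij = |cor|^beta, topological overlap, average-linkage clustering of
1 - TOM with a static cut and small-cluster merging.  Module eigengenes (first
principal component of the standardized module submatrix) are correlated with
condition indicators; modules are validated by permutation GSEA with the
weighted Kolmogorov-Smirnov enrichment statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from tcellgrn.io_preprocess import ExpressionMatrix

__all__ = [
    "SOMGrid",
    "ModuleAssignment",
    "ModuleEigengene",
    "EnrichmentResult",
    "most_variable_genes",
    "som_fit",
    "topological_overlap",
    "wgcna_modules",
    "module_eigengene",
    "module_trait_correlation",
    "gsea",
    "correlation_profile",
]


@dataclass
class SOMGrid:
    shape: tuple[int, int]
    prototypes: np.ndarray            # (rows*cols) x n_features
    assignment: pd.Series             # gene -> flat node index
    node_summary: pd.DataFrame        # node x feature mean profile of members
    quantization_errors: list[float]  # error at training checkpoints


@dataclass
class ModuleAssignment:
    labels: pd.Series                 # gene -> module id (0 = unassigned)
    linkage: np.ndarray | None = None

    @property
    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()

    def genes_of(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])


@dataclass
class ModuleEigengene:
    module: int
    scores: pd.Series                 # per-sample, unit norm
    orientation: int                  # +1/-1 applied to satisfy the sign rule


@dataclass
class EnrichmentResult:
    gene_set: str
    es: float
    nes: float
    p: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError("permutation p must lie in (0, 1]")
        if np.isfinite(self.nes) and self.es * self.nes < 0:
            raise ValueError("NES must carry the sign of ES")


def most_variable_genes(matrix: ExpressionMatrix, n: int, criterion: str = "sd") -> list[str]:
    """Top-n genes by per-gene standard deviation; exact ties break by id."""
    if criterion != "sd":
        raise ValueError(f"unknown criterion {criterion!r}")
    if n > len(matrix.genes):
        raise ValueError("n exceeds gene count")
    sd = matrix.values.std(axis=1, ddof=1)
    order = sorted(matrix.genes, key=lambda g: (-sd[g], g))
    return order[:n]


def som_fit(profiles: pd.DataFrame, grid: tuple[int, int] = (10, 10),
            iterations: int = 20_000, seed: int = 0,
            learning_rate: tuple[float, float] = (0.05, 0.01)) -> SOMGrid:
    """Online self-organizing map over standardized gene profiles.

    ``profiles`` is genes x features (per-cluster standardized mean
    expression).  Prototypes are initialized deterministically on the grid
    spanned by the first two principal loadings; training uses a Gaussian
    neighborhood whose radius decays linearly from max(grid)/2 to 0.5 and a
    linearly decaying learning rate, with seed-controlled sample order.  The
    per-node summary is the mean profile of the member genes.
    """
    X = profiles.to_numpy(float)
    if X.size == 0:
        raise ValueError("empty input to som_fit")
    n_genes, n_feat = X.shape
    rows, cols = grid
    n_nodes = rows * cols

    Xc = X - X.mean(axis=0, keepdims=True)
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    pc = np.zeros((2, n_feat))
    scale = S[: min(2, len(S))] / max(np.sqrt(n_genes), 1.0)
    pc[: min(2, len(S))] = Vt[: min(2, len(S))] * scale[:, None]
    a = np.linspace(-1.0, 1.0, rows) if rows > 1 else np.zeros(1)
    b = np.linspace(-1.0, 1.0, cols) if cols > 1 else np.zeros(1)
    prototypes = (a[:, None, None] * pc[0] + b[None, :, None] * pc[1]).reshape(n_nodes, n_feat)

    grid_pos = np.array([(i, j) for i in range(rows) for j in range(cols)], float)
    grid_d2 = ((grid_pos[:, None, :] - grid_pos[None, :, :]) ** 2).sum(axis=2)

    rng = np.random.default_rng(seed)
    radius0, radius1 = max(rows, cols) / 2.0, 0.5
    lr0, lr1 = learning_rate
    checkpoints = max(iterations // 10, 1)
    qerrors: list[float] = []

    def _qe() -> float:
        d = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
        return float(np.sqrt(d.min(axis=1)).mean())

    for t in range(iterations):
        frac = t / max(iterations - 1, 1)
        radius = radius0 + (radius1 - radius0) * frac
        lr = lr0 + (lr1 - lr0) * frac
        x = X[rng.integers(n_genes)]
        bmu = int(((prototypes - x) ** 2).sum(axis=1).argmin())
        h = np.exp(-grid_d2[bmu] / (2.0 * radius**2))
        prototypes += lr * h[:, None] * (x - prototypes)
        if (t + 1) % checkpoints == 0:
            qerrors.append(_qe())

    d = ((X[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    assignment = pd.Series(d.argmin(axis=1), index=profiles.index)
    summary = np.zeros((n_nodes, n_feat))
    for node, members in assignment.groupby(assignment).groups.items():
        summary[node] = X[[profiles.index.get_loc(g) for g in members]].mean(axis=0)
    node_summary = pd.DataFrame(summary, columns=profiles.columns)
    return SOMGrid(shape=grid, prototypes=prototypes, assignment=assignment,
                   node_summary=node_summary, quantization_errors=qerrors)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij); diag 1."""
    A = adjacency.copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def wgcna_modules(matrix: ExpressionMatrix, genes=None, beta: float = 15,
                  min_module_size: int = 10, cut_height: float = 0.99,
                  signed: bool = False) -> ModuleAssignment:
    """Topological-overlap co-expression modules.

    Unsigned adjacency |cor|^beta (or signed ((1+cor)/2)^beta), TOM distance,
    average-linkage tree cut statically at ``cut_height``; clusters smaller
    than ``min_module_size`` are merged into the module whose eigengene they
    correlate with best, and irreducible leftovers go to module 0.  Modules are
    numbered 1.. by decreasing size.
    """
    genes = list(genes) if genes is not None else matrix.genes
    if len(genes) < min_module_size:
        raise ValueError("fewer genes than min_module_size")
    sub = matrix.values.loc[genes]
    sd = sub.std(axis=1, ddof=0)
    if (sd == 0).any():
        dropped = list(sub.index[sd == 0])
        warnings.warn(f"wgcna_modules: dropping {len(dropped)} constant gene(s)")
        sub = sub[sd > 0]
        genes = list(sub.index)
    corr = np.corrcoef(sub.to_numpy(float))
    A = ((1 + corr) / 2.0) ** beta if signed else np.abs(corr) ** beta
    tom = topological_overlap(A)
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(Z, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)

    def _eigengene_scores(members: list[str]) -> np.ndarray:
        return _first_pc(sub.loc[members].to_numpy(float))

    # merge undersized clusters into the best-correlated large module
    while True:
        sizes = labels.value_counts()
        small = [c for c in sizes.index if sizes[c] < min_module_size]
        big = [c for c in sizes.index if sizes[c] >= min_module_size]
        if not small or not big:
            break
        me = {c: _eigengene_scores(list(labels.index[labels == c])) for c in sizes.index}
        c = min(small, key=lambda c: sizes[c])
        best = max(big, key=lambda o: abs(np.corrcoef(me[c], me[o])[0, 1]))
        labels[labels == c] = best
        if c != best:
            continue
        break

    sizes = labels.value_counts()
    keep = [c for c in sizes.index if sizes[c] >= min_module_size]
    order = sorted(keep, key=lambda c: (-sizes[c], c))
    relabel = {c: i + 1 for i, c in enumerate(order)}
    final = labels.map(lambda c: relabel.get(c, 0))
    return ModuleAssignment(labels=final, linkage=Z)


def _first_pc(values: np.ndarray) -> np.ndarray:
    """Unit-norm first right-singular vector of the row-standardized matrix."""
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    _, _, Vt = np.linalg.svd(z, full_matrices=False)
    v = Vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    return v / np.linalg.norm(v)


def module_eigengene(matrix: ExpressionMatrix, module_genes, module: int = 0) -> ModuleEigengene:
    """First principal component of the gene-standardized module submatrix.

    Oriented so its correlation with the module's mean standardized profile is
    non-negative; returned with unit norm.
    """
    module_genes = list(module_genes)
    if len(module_genes) < 2:
        raise ValueError("module_eigengene needs at least 2 genes")
    values = matrix.values.loc[module_genes].to_numpy(float)
    v = _first_pc(values)
    return ModuleEigengene(module=module, scores=pd.Series(v, index=matrix.samples), orientation=1)


def module_trait_correlation(eigengenes: pd.DataFrame,
                             trait_indicators: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r of each module eigengene with each 0/1 trait indicator.

    Returns (r, p) tables, p from the exact t-transform of r with n-2 degrees
    of freedom.
    """
    n = len(eigengenes)
    if n != len(trait_indicators):
        raise ValueError("eigengenes and traits must cover the same samples")
    E = eigengenes.to_numpy(float)
    T = trait_indicators.to_numpy(float)
    Ez = (E - E.mean(axis=0)) / E.std(axis=0)
    Tz = (T - T.mean(axis=0)) / T.std(axis=0)
    r = Ez.T @ Tz / n
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    idx, cols = eigengenes.columns, trait_indicators.columns
    return (pd.DataFrame(r, index=idx, columns=cols),
            pd.DataFrame(p, index=idx, columns=cols))


def _enrichment_score(stat: np.ndarray, is_hit: np.ndarray) -> float:
    """Weighted KS running-sum enrichment score (weight exponent 1).

    Genes ordered by decreasing statistic; hits advance the running sum in
    proportion to |stat|, misses retreat it uniformly; ES is the extremum.
    A set covering every gene has no miss pool and scores 0 by definition.
    """
    order = np.argsort(-stat, kind="stable")
    hit = is_hit[order]
    n_hit = int(hit.sum())
    n_miss = len(stat) - n_hit
    if n_hit == 0 or n_miss == 0:
        return 0.0
    w = np.abs(stat[order]) * hit
    total_w = w.sum()
    if total_w == 0:
        w = hit.astype(float)
        total_w = float(n_hit)
    running = np.cumsum(w / total_w - (~hit) / n_miss)
    return float(running[np.argmax(np.abs(running))])


def gsea(ranked_stats: pd.Series, gene_set, n_perm: int = 1000, seed: int = 0,
         matrix: ExpressionMatrix | None = None, labels=None,
         set_name: str = "") -> EnrichmentResult:
    """Permutation GSEA of one gene set against a ranked statistic.

    ``ranked_stats`` is the per-gene contrast statistic (e.g. Student t of a
    cluster-vs-rest comparison).  With ``matrix`` and binary ``labels`` given,
    the null is built by sample-label permutation (the statistic is recomputed
    per permutation); otherwise gene-label permutation is used.  NES is ES
    divided by the mean |ES*| of same-sign permutations and
    p = (1 + #{same sign, |ES*| >= |ES|}) / (n_same + 1).
    """
    gene_set = set(gene_set)
    genes = list(ranked_stats.index)
    is_hit = np.array([g in gene_set for g in genes])
    if not is_hit.any():
        raise ValueError("gene set does not intersect the ranked list")
    stat = ranked_stats.to_numpy(float)
    es = _enrichment_score(stat, is_hit)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    if matrix is not None and labels is not None:
        lab = np.asarray(labels, bool)
        vals = matrix.values.loc[genes].to_numpy(float)
        for i in range(n_perm):
            perm = rng.permutation(lab)
            null[i] = _enrichment_score(_pooled_t(vals, perm), is_hit)
    else:
        for i in range(n_perm):
            null[i] = _enrichment_score(stat, rng.permutation(is_hit))

    same = null[np.sign(null) == np.sign(es)] if es != 0 else null
    n_same = len(same)
    if n_same == 0:
        return EnrichmentResult(set_name, es, np.nan, 1.0, n_perm)
    nes = es / np.abs(same).mean() if np.abs(same).mean() > 0 else np.nan
    p = (1 + int((np.abs(same) >= abs(es)).sum())) / (n_same + 1)
    return EnrichmentResult(set_name, es, nes, p, n_perm)


def _pooled_t(values: np.ndarray, group_mask: np.ndarray) -> np.ndarray:
    """Vectorized pooled-variance t of group vs rest, per row."""
    g, r = values[:, group_mask], values[:, ~group_mask]
    n1, n2 = g.shape[1], r.shape[1]
    m1, m2 = g.mean(axis=1), r.mean(axis=1)
    ss = ((g - m1[:, None]) ** 2).sum(axis=1) + ((r - m2[:, None]) ** 2).sum(axis=1)
    se = np.sqrt(np.maximum(ss / (n1 + n2 - 2), 1e-12) * (1 / n1 + 1 / n2))
    return (m1 - m2) / se


def correlation_profile(matrix: ExpressionMatrix, query_gene: str) -> pd.DataFrame:
    """Pearson correlation of one gene against all others, ranked descending."""
    if query_gene not in matrix.values.index:
        raise KeyError(f"query gene {query_gene!r} not in matrix")
    X = matrix.values.to_numpy(float)
    q = matrix.values.loc[query_gene].to_numpy(float)
    qz = (q - q.mean()) / q.std()
    sd = X.std(axis=1)
    sd[sd == 0] = np.nan
    Xz = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    r = Xz @ qz / len(q)
    out = pd.DataFrame({"gene": matrix.genes, "r": r}).set_index("gene")
    out = out.drop(index=query_gene).dropna()
    return out.sort_values("r", ascending=False, kind="stable")
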