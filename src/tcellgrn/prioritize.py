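"""Candidate-TF prioritization, Borda combination and regulon filtering.

Hub genes are prioritized by similarity to a small set of well-characterized
training regulators along two independent axes — co-expression similarity
(mean |Pearson r|) and annotation similarity (mean Jaccard over term sets) —
and the two rankings are combined by the Borda method.  Regulon analysis
tests the overlap between a gene set and each TF's promoter motif-hit genes by
the hypergeometric distribution, and target filtering keeps module genes that
both carry the TF's motif and pass a fold-change gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from tcellgrn.differential import bh_fdr
from tcellgrn.io_preprocess import ExpressionMatrix

__all__ = [
    "filter_tfs",
    "coexpression_similarity_rank",
    "annotation_similarity_rank",
    "borda_combine",
    "expression_filter",
    "motif_enrichment",
    "target_filter",
    "read_motif_table",
    "write_motif_table",
]


def filter_tfs(genes, tf_catalogue) -> list[str]:
    """Intersection with the TF catalogue, preserving input order."""
    catalogue = set(tf_catalogue)
    if not catalogue:
        raise ValueError("empty TF catalogue")
    return [g for g in genes if g in catalogue]


def _ranked(scores: dict[str, float]) -> pd.DataFrame:
    """Descending-score table with averaged-tie fractional positions."""
    table = pd.DataFrame({"gene": list(scores), "score": list(scores.values())})
    table["position"] = stats.rankdata(-table["score"].to_numpy(), method="average")
    return table.sort_values(["position", "gene"], kind="stable").set_index("gene")


def coexpression_similarity_rank(matrix: ExpressionMatrix, candidates,
                                 training_genes) -> pd.DataFrame:
    """Rank candidates by mean |Pearson r| with the training regulators."""
    training = [g for g in training_genes if g in matrix.values.index]
    if not training:
        raise ValueError("no training gene present in the matrix")
    T = matrix.values.loc[training].to_numpy(float)
    Tz = (T - T.mean(axis=1, keepdims=True)) / T.std(axis=1, keepdims=True)
    scores: dict[str, float] = {}
    n = T.shape[1]
    for cand in candidates:
        x = matrix.values.loc[cand].to_numpy(float)
        sd = x.std()
        if sd == 0:
            scores[cand] = 0.0
            continue
        xz = (x - x.mean()) / sd
        r = Tz @ xz / n
        scores[cand] = float(np.abs(r).mean())
    return _ranked(scores)


def annotation_similarity_rank(annotation: dict[str, set[str]], candidates,
                               training_genes) -> pd.DataFrame:
    """Rank candidates by mean Jaccard term-set similarity to the training genes."""
    training_terms = []
    for t in training_genes:
        if t not in annotation:
            raise ValueError(f"training gene {t!r} missing from the annotation table")
        training_terms.append(set(annotation[t]))
    scores: dict[str, float] = {}
    for cand in candidates:
        terms = set(annotation.get(cand, set()))
        if not terms:
            scores[cand] = 0.0
            continue
        sims = [len(terms & tt) / len(terms | tt) if terms | tt else 0.0
                for tt in training_terms]
        scores[cand] = float(np.mean(sims))
    return _ranked(scores)


def borda_combine(rankings: list[pd.DataFrame]) -> pd.DataFrame:
    """Borda score = sum over lists of (N - position); ties share averaged positions.

    All rankings must cover the same candidate set.  The final order is by
    descending Borda score, ties broken by gene id.
    """
    if len(rankings) < 2:
        raise ValueError("borda_combine needs at least 2 rankings")
    candidates = set(rankings[0].index)
    for r in rankings[1:]:
        if set(r.index) != candidates:
            raise ValueError("rankings cover different candidate sets")
    N = len(candidates)
    borda = pd.Series(0.0, index=sorted(candidates))
    for r in rankings:
        borda += (N - r["position"]).reindex(borda.index)
    out = pd.DataFrame({"borda": borda})
    out = out.loc[sorted(out.index, key=lambda g: (-out.loc[g, "borda"], g))]
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def expression_filter(prioritized, matrix: ExpressionMatrix, top_n: int,
                      head: int | None = None) -> list[str]:
    """Keep the most highly expressed genes among the prioritized head.

    ``prioritized`` is an ordered gene list; the first ``head`` entries (all by
    default) are re-ranked by mean expression across samples and the top_n
    survive, in descending mean-expression order.
    """
    candidates = list(prioritized)[: head if head is not None else None]
    if top_n > len(candidates):
        raise ValueError("top_n exceeds candidate count")
    means = matrix.values.loc[candidates].mean(axis=1)
    ordered = sorted(candidates, key=lambda g: (-means[g], g))
    return ordered[:top_n]


def motif_enrichment(gene_set, hit_table: pd.DataFrame, universe) -> pd.DataFrame:
    """One-sided hypergeometric promoter-motif enrichment per TF.

    For each TF column of the boolean gene x TF ``hit_table``, the overlap
    between ``gene_set`` and the TF's hit genes (within ``universe``) is scored
    by the hypergeometric upper tail; q is BH across TFs.  The overlap genes
    are the TF's predicted regulon inside the set.
    """
    universe = list(dict.fromkeys(universe))
    uni_set = set(universe)
    gene_set = set(gene_set)
    if not gene_set <= uni_set:
        raise ValueError("gene_set must be contained in the universe")
    M, n = len(universe), len(gene_set)
    rows = []
    hits = hit_table.reindex(universe).fillna(False).astype(bool)
    for tf in hits.columns:
        tf_genes = set(hits.index[hits[tf]])
        K = len(tf_genes)
        overlap = sorted(tf_genes & gene_set)
        k = len(overlap)
        p = 1.0 if K == 0 else float(stats.hypergeom.sf(k - 1, M, K, n))
        rows.append({"tf": tf, "overlap": k, "hits_in_universe": K,
                     "p": min(p, 1.0), "regulon": ",".join(overlap)})
    table = pd.DataFrame(rows).set_index("tf")
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table.sort_values(["p", "tf"], kind="stable")[
        ["overlap", "hits_in_universe", "p", "q", "regulon"]]


def target_filter(hit_table: pd.DataFrame, tf: str, module_genes,
                  de_records: pd.DataFrame, fc_threshold: float = 1.0) -> list[str]:
    """Module genes carrying the TF's motif hit with |FC| strictly above the gate."""
    if tf not in hit_table.columns:
        raise KeyError(f"TF {tf!r} not in hit table")
    out = []
    for gene in module_genes:
        if gene not in de_records.index:
            raise ValueError(f"module gene {gene!r} missing from DE records")
        has_hit = bool(hit_table.loc[gene, tf]) if gene in hit_table.index else False
        if has_hit and abs(float(de_records.loc[gene, "fc"])) > fc_threshold:
            out.append(gene)
    return out


def read_motif_table(path) -> pd.DataFrame:
    """Read a TSV motif-hit table: first column gene, remaining columns TFs, cells 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(int).astype(bool)


def write_motif_table(hit_table: pd.DataFrame, path) -> None:
    hit_table.astype(int).to_csv(path, sep="\t", index_label="gene")
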