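"""Differential expression between condition clusters and a resting reference.

Per-gene pooled-variance Student's t (two groups) or two-way fixed-effects
ANOVA (condition + batch, no interaction), Benjamini-Hochberg FDR, the
|FC| > 2 & q < 0.05 gate, and UpSet-style exclusive-intersection accounting.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from tcellgrn.io_preprocess import ExpressionMatrix
from tcellgrn.sample_structure import signed_fold_change

__all__ = [
    "t_test_contrast",
    "anova_two_way",
    "bh_fdr",
    "de_genes",
    "upset_intersections",
]

_VAR_FLOOR = 1e-12


def t_test_contrast(matrix: ExpressionMatrix, group_samples, ref_samples,
                    contrast: str = "") -> pd.DataFrame:
    """Two-sided pooled-variance Student's t per gene, group vs reference.

    Returns a record table with the log2 difference ``delta`` (group minus
    reference), the signed linear fold change, t statistic, raw p and
    BH-adjusted q.  For genes where both groups are identical and constant the
    statistic is 0 and p = 1; otherwise a variance floor guards against
    division by zero.
    """
    g = matrix.values[list(group_samples)].to_numpy(float)
    r = matrix.values[list(ref_samples)].to_numpy(float)
    n1, n2 = g.shape[1], r.shape[1]
    if min(n1, n2) < 2:
        raise ValueError("both groups need at least 2 samples")
    m1, m2 = g.mean(axis=1), r.mean(axis=1)
    ss1 = ((g - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((r - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled = (ss1 + ss2) / df
    delta = m1 - m2
    degenerate = (pooled <= _VAR_FLOOR) & (np.abs(delta) <= _VAR_FLOOR)
    floored = (pooled <= _VAR_FLOOR) & ~degenerate
    if floored.any():
        warnings.warn("t_test_contrast: zero pooled variance floored for some genes")
    se = np.sqrt(np.maximum(pooled, _VAR_FLOOR) * (1.0 / n1 + 1.0 / n2))
    t = np.where(degenerate, 0.0, delta / se)
    p = np.where(degenerate, 1.0, 2.0 * stats.t.sf(np.abs(t), df))
    q = bh_fdr(p)
    return pd.DataFrame({
        "gene": matrix.genes,
        "delta": delta,
        "fc": signed_fold_change(delta),
        "stat": t,
        "p": p,
        "q": q,
        "contrast": contrast,
    }).set_index("gene")


def anova_two_way(matrix: ExpressionMatrix, condition_factor, batch_factor=None) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA (condition + batch, no interaction) per gene.

    Type-II sums of squares by least squares on the dummy-coded design: the
    condition effect is RSS(batch-only) minus RSS(full).  With a single batch
    level this degrades to one-way ANOVA.  Reports the condition-effect F, raw
    p and BH-adjusted q.
    """
    cond = pd.Categorical(np.asarray(condition_factor))
    if len(cond.categories) < 2:
        raise ValueError("condition factor needs at least 2 levels")
    Y = matrix.values.to_numpy(float).T  # samples x genes
    n = Y.shape[0]
    parts = [np.ones((n, 1)), pd.get_dummies(cond, drop_first=True).to_numpy(float)]
    reduced_parts = [np.ones((n, 1))]
    if batch_factor is not None:
        batch = pd.Categorical(np.asarray(batch_factor))
        if len(batch.categories) > 1:
            B = pd.get_dummies(batch, drop_first=True).to_numpy(float)
            parts.append(B)
            reduced_parts.append(B)
    X_full = np.hstack(parts)
    X_red = np.hstack(reduced_parts)

    def _rss_and_rank(X):
        Q, R = np.linalg.qr(X)
        rank = int(np.sum(np.abs(np.diag(R)) > 1e-10))
        fitted = Q @ (Q.T @ Y)
        return ((Y - fitted) ** 2).sum(axis=0), rank

    rss_full, rank_full = _rss_and_rank(X_full)
    rss_red, rank_red = _rss_and_rank(X_red)
    df_cond = rank_full - rank_red
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_resid = np.maximum(rss_full / df_resid, _VAR_FLOOR)
    F = np.maximum(rss_red - rss_full, 0.0) / df_cond / ms_resid
    p = stats.f.sf(F, df_cond, df_resid)
    return pd.DataFrame({
        "gene": matrix.genes,
        "stat": F,
        "p": p,
        "q": bh_fdr(p),
        "df_condition": df_cond,
        "df_resid": df_resid,
    }).set_index("gene")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values with enforced monotonicity."""
    p = np.asarray(p_values, float)
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_genes(records: pd.DataFrame, fc_threshold: float = 2.0,
             q_threshold: float = 0.05) -> set[str]:
    """The classical gate: |FC| strictly above 2 and q strictly below 0.05."""
    mask = (records["fc"].abs() > fc_threshold) & (records["q"] < q_threshold)
    return set(records.index[mask])


def upset_intersections(named_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive membership-pattern counts over named gene sets.

    Every gene in the union is counted in exactly one pattern (the full tuple
    of sets it belongs to), so pattern counts always sum to the union size.
    """
    if not named_sets:
        raise ValueError("at least one set required")
    names = list(named_sets)
    pattern_members: dict[tuple[str, ...], set] = {}
    for gene in set().union(*named_sets.values()):
        pattern = tuple(n for n in names if gene in named_sets[n])
        pattern_members.setdefault(pattern, set()).add(gene)
    rows = [
        {"pattern": "&".join(p), "degree": len(p), "count": len(members)}
        for p, members in sorted(pattern_members.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    ]
    table = pd.DataFrame(rows)
    assert table["count"].sum() == len(set().union(*named_sets.values()))
    return table
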