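"""Expression-matrix I/O and microarray-style preprocessing.

The preprocessing chain mirrors standard microarray practice on log2-scale
intensity data: quantile normalization across samples, estimation of a
dataset-wide background threshold, removal of never-expressed genes, collapse
of duplicated probes to one representative per gene, and per-batch mean
centering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "quantile_normalize",
    "estimate_background",
    "filter_expressed",
    "collapse_probes",
    "center_batches",
]


@dataclass
class ExpressionMatrix:
    """Log2 expression values, rows = probes or genes, columns = samples.

    ``gene_map`` maps probe id -> gene symbol; it is ``None`` once probes have
    been collapsed (row ids are then gene symbols).
    """

    values: pd.DataFrame
    gene_map: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.gene_map is not None:
            self.gene_map = self.gene_map.reindex(self.values.index)
            if self.gene_map.isna().any():
                missing = self.gene_map[self.gene_map.isna()].index[0]
                raise ValueError(f"probe {missing!r} missing from probe->gene map")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: pd.DataFrame, gene_map: pd.Series | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, gene_map=gene_map)


GENE_COLUMN = "gene"


def read_expression(path, probe_gene_map: pd.Series | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Layout: header row of sample ids, first column row ids (probe or gene);
    an optional second column named ``gene`` carries the probe->gene map.
    Duplicate sample ids, non-numeric cells and missing values are rejected
    with the offending row/column named.
    """
    with open(path) as fh:
        header = fh.readline()
        while header.startswith("#"):
            header = fh.readline()
    names = header.rstrip("\n").split("\t")[1:]
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate sample id {name!r} in {path}")
        seen.add(name)
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    gene_map = probe_gene_map
    if len(df.columns) and df.columns[0] == GENE_COLUMN:
        gene_map = df[GENE_COLUMN].astype(str)
        df = df.drop(columns=[GENE_COLUMN])
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in column {col!r}, row {bad[bad].index[0]!r}"
            )
        if numeric.isna().any():
            raise ValueError(
                f"missing value in column {col!r}, row {numeric[numeric.isna()].index[0]!r}"
            )
        df[col] = numeric.astype(float)
    return ExpressionMatrix(values=df, gene_map=gene_map)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the matrix as TSV; a ``gene`` column is emitted when a map exists."""
    df = matrix.values
    if matrix.gene_map is not None:
        df = df.copy()
        df.insert(0, GENE_COLUMN, matrix.gene_map)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def read_samples(path) -> pd.DataFrame:
    """Read the sample annotation table (sample, condition, batch[, cluster])."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"sample", "condition", "batch"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample annotation missing columns: {sorted(missing)}")
    if df["sample"].duplicated().any():
        raise ValueError("duplicate sample ids in annotation")
    if (df["condition"].str.len() == 0).any():
        raise ValueError("empty condition label in annotation")
    return df.set_index("sample")


def write_samples(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common per-rank mean distribution.

    After normalization each column, sorted, equals the reference vector (the
    mean across columns of the sorted values).  Values tied within a column all
    receive the mean of the reference values at the ranks they jointly occupy.
    """
    vals = matrix.values.to_numpy(float)
    n_rows, n_cols = vals.shape
    if n_cols < 2:
        warnings.warn("quantile_normalize: single-column matrix returned unchanged")
        return matrix.copy_with(matrix.values.copy(), matrix.gene_map)
    ref = np.sort(vals, axis=0).mean(axis=1)
    ref_cumsum = np.concatenate([[0.0], np.cumsum(ref)])
    out = np.empty_like(vals)
    for j in range(n_cols):
        col = vals[:, j]
        uniq, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        group_means = (ref_cumsum[starts + counts] - ref_cumsum[starts]) / counts
        out[:, j] = group_means[inverse]
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values, matrix.gene_map)


def estimate_background(matrix: ExpressionMatrix, override: float | None = None) -> float:
    """Estimate the dataset-wide background expression threshold tau.

    A two-component Gaussian mixture is fitted to the per-row mean expression;
    tau is the point between the component means where the posterior
    responsibility flips from the background to the signal component.  When the
    mixture collapses onto a single mode (component means closer than the wider
    component's standard deviation) there is no detectable background
    population and the 10th percentile of row means is returned instead.
    Passing ``override`` returns it verbatim.
    """
    if override is not None:
        return float(override)
    means = matrix.values.mean(axis=1).to_numpy(float)
    if np.ptp(means) == 0.0:
        raise ValueError("cannot estimate background from a constant matrix")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=0)
    gm.fit(means.reshape(-1, 1))
    mu = gm.means_.ravel()
    sd = np.sqrt(gm.covariances_.ravel())
    lo, hi = np.argsort(mu)
    # Ashman's D < 2: the two components do not describe separable modes
    ashman_d = np.sqrt(2.0) * (mu[hi] - mu[lo]) / np.sqrt(sd[lo] ** 2 + sd[hi] ** 2)
    if ashman_d < 2.0:
        warnings.warn("estimate_background: no separable background component; "
                      "falling back to the 10th percentile of row means")
        return float(np.percentile(means, 10.0))
    grid = np.linspace(mu[lo], mu[hi], 2001)
    post = gm.predict_proba(grid.reshape(-1, 1))
    flip = np.argmax(post[:, hi] >= 0.5)
    return float(grid[flip])


def filter_expressed(matrix: ExpressionMatrix, tau: float) -> ExpressionMatrix:
    """Keep rows exceeding the background threshold in at least one sample."""
    keep = (matrix.values.to_numpy(float) > tau).any(axis=1)
    gene_map = matrix.gene_map[keep] if matrix.gene_map is not None else None
    return matrix.copy_with(matrix.values.loc[keep], gene_map)


def collapse_probes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene, the probe with the highest mean expression.

    Exact mean ties are broken by the lexicographically smallest probe id so
    the collapse is deterministic across platforms.  Output row ids are gene
    symbols, in order of first appearance.
    """
    if matrix.gene_map is None:
        raise ValueError("collapse_probes requires a probe->gene map")
    means = matrix.values.mean(axis=1)
    table = pd.DataFrame({
        "probe": matrix.values.index,
        "gene": matrix.gene_map.to_numpy(),
        "mean": means.to_numpy(),
    })
    table = table.sort_values(["mean", "probe"], ascending=[False, True], kind="stable")
    winners = table.drop_duplicates("gene")
    first_seen = {g: i for i, g in enumerate(dict.fromkeys(matrix.gene_map))}
    winners = winners.sort_values("gene", key=lambda s: s.map(first_seen), kind="stable")
    values = matrix.values.loc[winners["probe"]].copy()
    values.index = winners["gene"].to_numpy()
    return ExpressionMatrix(values=values, gene_map=None)


def center_batches(matrix: ExpressionMatrix, annotation: pd.DataFrame) -> ExpressionMatrix:
    """Shift each batch's per-gene mean onto the gene's grand mean.

    The per-gene grand mean is preserved; after centering, between-batch mean
    variance is zero for every gene.
    """
    batches = annotation.loc[matrix.samples, "batch"]
    vals = matrix.values.to_numpy(float)
    grand = vals.mean(axis=1, keepdims=True)
    out = vals.copy()
    for batch, cols in batches.groupby(batches).groups.items():
        idx = [matrix.samples.index(s) for s in cols]
        if len(idx) == 1:
            warnings.warn(f"center_batches: batch {batch!r} has a single sample")
        batch_mean = vals[:, idx].mean(axis=1, keepdims=True)
        out[:, idx] += grand - batch_mean
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return matrix.copy_with(values, matrix.gene_map)
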