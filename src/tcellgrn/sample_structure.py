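"""Sample-level structure: PCA, condition correlation matrices, clustering.

Pairwise Pearson correlation between condition profiles (the CCM), cut by
average-linkage hierarchical clustering into condition clusters, plus k-means
over fold-change profiles with Davies-Bouldin model selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score

from tcellgrn.io_preprocess import ExpressionMatrix

__all__ = [
    "PCAResult",
    "ClusterAssignment",
    "pca",
    "signed_fold_change",
    "correlation_matrix",
    "hierarchical_cluster",
    "kmeans_davies_bouldin",
]


@dataclass
class PCAResult:
    scores: pd.DataFrame          # units (samples) x k
    loadings: pd.DataFrame        # genes x k
    explained_variance_ratio: np.ndarray

    def __post_init__(self) -> None:
        evr = self.explained_variance_ratio
        if np.any(np.diff(evr) > 1e-12) or evr.sum() > 1 + 1e-9:
            raise ValueError("explained-variance fractions must be non-increasing and sum <= 1")


@dataclass
class ClusterAssignment:
    labels: pd.Series             # unit id -> cluster id, contiguous from 1
    linkage: np.ndarray | None = None
    method: str = ""

    def __post_init__(self) -> None:
        ids = sorted(set(self.labels))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("cluster ids must be contiguous from 1")


def pca(matrix: ExpressionMatrix, k: int) -> PCAResult:
    """Mean-centered SVD of the samples-by-genes matrix.

    Deterministic up to sign; each component's sign is fixed by making the
    largest-magnitude entry of its loading vector positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    X = matrix.values.to_numpy(float).T  # samples x genes
    if k > min(X.shape):
        raise ValueError("k exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U[:, :k] * S[:k]
    total_var = (S**2).sum()
    evr = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    comp = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.samples, columns=comp),
        loadings=pd.DataFrame(Vt[:k].T, index=matrix.genes, columns=comp),
        explained_variance_ratio=evr,
    )


def signed_fold_change(delta: np.ndarray | float):
    """Signed linear fold change from a log2 difference.

    FC = 2**d for d >= 0 and -2**(-d) otherwise, so the classical gate
    |FC| > 2 is exactly |d| > 1.
    """
    d = np.asarray(delta, float)
    fc = np.where(d >= 0, 2.0**d, -(2.0 ** (-d)))
    return fc if fc.ndim else float(fc)


def correlation_matrix(matrix: ExpressionMatrix, annotation: pd.DataFrame | None = None,
                       group_by_condition: bool = False) -> pd.DataFrame:
    """Pairwise Pearson correlation over all present genes.

    With ``group_by_condition`` the profiles are per-condition means of the
    member samples; otherwise per-sample columns are correlated directly.
    """
    values = matrix.values
    if group_by_condition:
        if annotation is None:
            raise ValueError("annotation required to group by condition")
        cond = annotation.loc[matrix.samples, "condition"]
        values = values.T.groupby(cond, sort=True).mean().T
    profiles = values.to_numpy(float)
    sd = profiles.std(axis=0)
    if np.any(sd == 0):
        bad = values.columns[np.argmax(sd == 0)]
        raise ValueError(f"zero-variance profile for {bad!r}")
    ccm = np.corrcoef(profiles, rowvar=False)
    np.fill_diagonal(ccm, 1.0)
    return pd.DataFrame(ccm, index=values.columns, columns=values.columns)


def hierarchical_cluster(ccm: pd.DataFrame, n_clusters: int,
                         method: str = "average") -> ClusterAssignment:
    """Cluster the rows of the z-scored CCM with Euclidean distance.

    The correlation matrix is standardized to mean 0 / sd 1 (matrix-wide), its
    rows clustered by the chosen linkage (default average/UPGMA), and the tree
    cut into ``n_clusters`` groups, relabelled contiguously from 1 in order of
    first appearance.
    """
    n = len(ccm)
    if n_clusters > n:
        raise ValueError("n_clusters exceeds number of units")
    z = (ccm.to_numpy(float) - ccm.to_numpy().mean()) / ccm.to_numpy().std()
    Z = linkage(z, method=method, metric="euclidean")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    relabel: dict[int, int] = {}
    labels = []
    for r in raw:
        relabel.setdefault(r, len(relabel) + 1)
        labels.append(relabel[r])
    return ClusterAssignment(labels=pd.Series(labels, index=ccm.index), linkage=Z, method=method)


def kmeans_davies_bouldin(data: pd.DataFrame, k_range, n_init: int = 10,
                          seed: int = 0) -> tuple[int, ClusterAssignment, pd.DataFrame]:
    """Lloyd's k-means over a k range with Davies-Bouldin model selection.

    ``data`` is units x features (typically fold-change profiles).  For each k
    the best of ``n_init`` seeded restarts (lowest inertia) is kept and scored
    with the Davies-Bouldin index; the k minimizing DB wins.
    """
    X = data.to_numpy(float)
    n = len(X)
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if not ks:
        raise ValueError("k_range must contain values in [2, n-1]")
    rows, fits = [], {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
        if len(set(labels)) < k:
            continue  # persistent empty cluster: drop this k
        db = davies_bouldin_score(X, labels)
        rows.append({"k": k, "db_index": db, "inertia": km.inertia_})
        fits[k] = labels
    if not rows:
        raise ValueError("no k in range produced a valid clustering")
    curve = pd.DataFrame(rows).set_index("k")
    best_k = int(curve["db_index"].idxmin())
    labels = fits[best_k]
    relabel: dict[int, int] = {}
    out = []
    for r in labels:
        relabel.setdefault(int(r), len(relabel) + 1)
        out.append(relabel[int(r)])
    assignment = ClusterAssignment(labels=pd.Series(out, index=data.index), method=f"kmeans(k={best_k})")
    return best_k, assignment, curve
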