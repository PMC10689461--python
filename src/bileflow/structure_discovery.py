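"""Sample embedding and clustering behind the heatmap/PCA views.

PCA embeds samples using proteins as features (centered, optionally
unit-scaled); component signs are fixed deterministically.  Protein rows
of the z-scored matrix are partitioned with Euclidean k-means (best of
``n_init`` seeded starts) and heatmap leaf orders come from agglomerative
clustering with average linkage on Euclidean distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .io_model import BileflowError, IntensityMatrix

logger = logging.getLogger("bileflow")


@dataclass
class Embedding:
    """Per-sample coordinates on ordered principal components."""

    coordinates: pd.DataFrame  # samples x components
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # proteins x components


def pca(
    matrix: IntensityMatrix,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> Embedding:
    """Principal component analysis of samples (proteins as features).

    Components come from the SVD of the centered (optionally unit-scaled)
    samples x proteins matrix; each component's sign is fixed by making
    its largest-magnitude loading positive so runs are deterministic.
    """
    X = matrix.values.T.astype(float)  # samples x proteins
    n_samples, n_features = X.shape
    if n_samples < 2:
        raise BileflowError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1 if center else n_samples, n_features)
    if n_components is None:
        n_components = max_comp
    elif n_components > max_comp:
        logger.warning(
            "requested %d components but only %d available; truncating",
            n_components, max_comp,
        )
        n_components = max_comp
    if center:
        X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    total_var = (S**2).sum()
    frac = (S**2) / total_var if total_var > 0 else np.zeros_like(S)
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return Embedding(
        coordinates=pd.DataFrame(
            scores[:, :n_components], index=matrix.sample_ids, columns=comp_names
        ),
        variance_fractions=frac[:n_components],
        loadings=pd.DataFrame(
            Vt[:n_components].T, index=matrix.protein_ids, columns=comp_names
        ),
    )


@dataclass
class RowClustering:
    labels: pd.Series  # per protein, in 1..k
    k: int
    seed: int
    inertia: float  # within-cluster sum of squares


def kmeans_rows(
    z_matrix: IntensityMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 10,
) -> RowClustering:
    """Euclidean k-means over protein rows, best of ``n_init`` starts.

    Cluster labels are renumbered canonically (ascending centroid mean)
    so runs on the same data are comparable.
    """
    if k < 2:
        raise BileflowError("k must be >= 2")
    n_rows = len(z_matrix.protein_ids)
    if k > n_rows:
        raise BileflowError(f"k={k} exceeds the {n_rows} proteins")
    X = z_matrix.values.astype(float)
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    order = np.argsort(km.cluster_centers_.mean(axis=1), kind="stable")
    remap = {int(old): rank + 1 for rank, old in enumerate(order)}
    labels = pd.Series(
        [remap[int(l)] for l in raw], index=z_matrix.data.index, name="cluster"
    )
    return RowClustering(labels, k, seed, float(km.inertia_))


def hclust_order(
    matrix: IntensityMatrix,
    axis: str = "columns",
    method: str = "average",
) -> list[str]:
    """Dendrogram leaf order from agglomerative clustering.

    Euclidean distance, average linkage by default; returns the ids on
    the chosen axis in dendrogram order for heatmap export.  Purely
    deterministic.
    """
    if axis not in ("rows", "columns"):
        raise BileflowError("axis must be 'rows' or 'columns'")
    X = matrix.values if axis == "rows" else matrix.values.T
    ids = matrix.protein_ids if axis == "rows" else matrix.sample_ids
    if X.shape[0] < 2:
        raise BileflowError("need at least 2 items to cluster")
    Z = linkage(pdist(X, metric="euclidean"), method=method)
    return [ids[i] for i in leaves_list(Z)]


def heatmap_export(
    z_matrix: IntensityMatrix,
    row_clusters: RowClustering | None = None,
    column_order: list[str] | None = None,
) -> pd.DataFrame:
    """Z-score table reordered for heatmap rendering.

    Rows are grouped by k-means cluster (cluster id column appended) and
    columns follow the hierarchical leaf order when given.
    """
    df = z_matrix.data.copy()
    if column_order is not None:
        df = df[column_order]
    if row_clusters is not None:
        df = df.assign(cluster=row_clusters.labels).sort_values(
            "cluster", kind="stable"
        )
    return df
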