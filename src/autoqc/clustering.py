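"""Metric-space embedding and QC clustering.

Cells are embedded in the (up to) 8-dimensional space of their QC metrics —
not gene-expression space — standardized per sample, connected by a kNN
graph (Euclidean) and partitioned by Leiden community detection at low
resolution.  The resulting communities are the "QC clusters" that later act
as the voting units for the two-step pass/fail decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateSampleError
from .qc_metrics import METRIC_COLUMNS


def knn_graph_edges(X: np.ndarray, k: int) -> list[tuple[int, int]]:
    """Undirected edge list of the symmetrized k-nearest-neighbour graph."""
    nn = NearestNeighbors(n_neighbors=min(k + 1, X.shape[0])).fit(X)
    _, idx = nn.kneighbors(X)
    edges = set()
    for i in range(X.shape[0]):
        for j in idx[i, 1:]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if a != b:
                edges.add((a, b))
    return sorted(edges)


def leiden_cluster(X: np.ndarray, k: int, resolution: float, seed: int) -> np.ndarray:
    """Leiden partition of the kNN graph of rows of X; deterministic per seed."""
    edges = knn_graph_edges(X, k)
    g = ig.Graph(n=X.shape[0], edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=-1,
    )
    return np.asarray(part.membership, dtype=int)


@dataclass
class ClusterResult:
    """Per-cell QC cluster assignment plus diagnostic layout coordinates."""

    cluster_id: np.ndarray
    layout: np.ndarray | None
    used_metrics: list[str]
    dropped_metrics: list[str]
    imputed_medians: dict[str, float] = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return int(self.cluster_id.max()) + 1


def embed_and_cluster(
    metrics: pd.DataFrame,
    k_neighbors: int = 15,
    resolution: float = 0.2,
    seed: int = 0,
    layout: str = "pca",
    metric_columns: list[str] | None = None,
) -> ClusterResult:
    """Standardize QC metrics, build a kNN graph and find QC clusters.

    Missing metric values are median-imputed (per sample, for the embedding
    only); metrics that are entirely missing or have zero variance are
    dropped.  Raises :class:`DegenerateSampleError` when fewer than
    ``max(k_neighbors + 1, 10)`` cells are available or no metric carries
    signal.

    ``layout`` is ``"pca"`` (default, deterministic), ``"umap"`` or
    ``"none"``; the coordinates are diagnostic only.
    """
    cols = metric_columns or METRIC_COLUMNS
    n = len(metrics)
    if n < max(k_neighbors + 1, 10):
        raise DegenerateSampleError(
            f"{n} cells is too few to cluster with k_neighbors={k_neighbors}"
        )

    X = metrics[cols].to_numpy(dtype=float)
    used, dropped, medians = [], [], {}
    columns = []
    for j, name in enumerate(cols):
        col = X[:, j]
        if np.all(~np.isfinite(col)):
            dropped.append(name)
            continue
        med = float(np.nanmedian(col))
        col = np.where(np.isfinite(col), col, med)
        sd = col.std()
        if sd == 0:
            dropped.append(name)
            continue
        medians[name] = med
        used.append(name)
        columns.append((col - col.mean()) / sd)
    if not used:
        raise DegenerateSampleError("all QC metrics are missing or zero-variance")
    Z = np.column_stack(columns)

    labels = leiden_cluster(Z, k_neighbors, resolution, seed)

    coords: np.ndarray | None = None
    if layout == "pca":
        coords = PCA(n_components=min(2, Z.shape[1]), random_state=seed).fit_transform(Z)
        if coords.shape[1] == 1:
            coords = np.column_stack([coords[:, 0], np.zeros(len(coords))])
    elif layout == "umap":
        import umap

        coords = umap.UMAP(
            n_neighbors=k_neighbors, n_components=2, random_state=int(seed)
        ).fit_transform(Z)
    elif layout != "none":
        raise ValueError(f"unknown layout method {layout!r}")

    return ClusterResult(
        cluster_id=labels,
        layout=coords,
        used_metrics=used,
        dropped_metrics=dropped,
        imputed_medians=medians,
    )
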