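"""Spatial feature selection, clustering and marker detection.

Spatial variability is scored with Moran's I on a symmetric binary
k-nearest-neighbour graph over array coordinates; per-sample top-k gene
lists are merged by union. Spots are clustered on PCA components of the
merged normalized matrix with Leiden community detection on a kNN graph,
and cluster markers are called by one-vs-rest rank-sum tests gated on
log2 fold change and p-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .errors import DegenerateDataWarning, ValidationError
from .stats import log2fc, rank_sum_matrix

__all__ = [
    "SpatialWeights",
    "knn_weights",
    "morans_i",
    "morans_i_matrix",
    "select_svgs",
    "cluster_spots",
    "find_markers",
]


@dataclass
class SpatialWeights:
    """Symmetric binary spatial adjacency with zero diagonal."""

    matrix: sparse.csr_matrix

    def __post_init__(self) -> None:
        w = sparse.csr_matrix(self.matrix)
        if (w != w.T).nnz:
            raise ValidationError("spatial weights must be symmetric")
        if w.diagonal().any():
            raise ValidationError("spatial weights must have a zero diagonal")
        self.matrix = w

    @property
    def n_spots(self) -> int:
        return self.matrix.shape[0]

    @property
    def total_weight(self) -> float:
        return float(self.matrix.sum())

    @property
    def isolated(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=1)).ravel() == 0


def knn_weights(coords: np.ndarray, k: int = 6) -> SpatialWeights:
    """Binary kNN adjacency on array coordinates, symmetrized by union."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] <= k:
        raise ValidationError(f"need more than k={k} spots to build a kNN graph")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    a = nn.kneighbors_graph(coords, mode="connectivity")
    a = a.tolil()
    a.setdiag(0)
    a = a.tocsr()
    a = ((a + a.T) > 0).astype(float)
    return SpatialWeights(sparse.csr_matrix(a))


def morans_i(values, weights: SpatialWeights) -> float:
    """Moran's spatial autocorrelation I of one per-spot variable.

    I = (N / W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with centered z.
    Raises on constant input, for which the statistic is undefined.
    """
    z = np.asarray(values, dtype=float).ravel()
    if z.size < 3:
        raise ValidationError("morans_i requires at least 3 spots")
    if z.size != weights.n_spots:
        raise ValidationError("values and weights disagree on spot count")
    z = z - z.mean()
    denom = float(z @ z)
    if denom == 0.0:
        raise ValidationError("morans_i is undefined for constant values")
    num = float(z @ (weights.matrix @ z))
    return (z.size / weights.total_weight) * (num / denom)


def morans_i_matrix(X: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    """Column-wise Moran's I; constant columns get NaN."""
    X = np.asarray(X, dtype=float)
    Z = X - X.mean(axis=0, keepdims=True)
    denom = (Z**2).sum(axis=0)
    num = (Z * (weights.matrix @ Z)).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (X.shape[0] / weights.total_weight) * (num / denom)
    out[denom == 0.0] = np.nan
    return out


def select_svgs(
    samples: dict[str, pd.DataFrame],
    coords: dict[str, np.ndarray],
    k_top: int = 500,
    k_neighbors: int = 6,
) -> list[str]:
    """Union of per-sample top-``k_top`` spatially variable genes.

    ``samples`` maps sample id to a normalized barcode x gene DataFrame;
    ``coords`` to the matching (n_spots, 2) array coordinates. Within a
    sample genes are ranked by Moran's I descending, ties broken by gene
    id; constant genes are unscorable. The union is returned sorted.
    """
    union: set[str] = set()
    for sid, X in samples.items():
        w = knn_weights(coords[sid], k=k_neighbors)
        scores = morans_i_matrix(X.to_numpy(), w)
        tbl = pd.DataFrame({"gene": X.columns, "score": scores}).dropna()
        if len(tbl) < k_top:
            warnings.warn(
                f"sample {sid}: only {len(tbl)} scorable genes (< k_top={k_top})",
                DegenerateDataWarning,
                stacklevel=2,
            )
        tbl = tbl.sort_values(["score", "gene"], ascending=[False, True])
        union.update(tbl["gene"].head(k_top))
    return sorted(union)


def cluster_spots(
    X: np.ndarray,
    n_pcs: int = 13,
    seed: int = 0,
    k_neighbors: int = 15,
    resolution: float = 0.5,
) -> np.ndarray:
    """Cluster spots by Leiden community detection on a PCA-kNN graph.

    Deterministic for a fixed seed. ``X`` is a spots x features matrix
    (typically the merged normalized matrix restricted to the spatially
    variable genes).
    """
    import igraph
    import leidenalg

    X = np.asarray(X, dtype=float)
    if X.shape[0] < n_pcs + 1:
        raise ValidationError("need at least n_pcs + 1 spots to cluster")
    if float(X.var()) == 0.0:
        raise ValidationError("cannot cluster a zero-variance matrix")
    n_pcs = min(n_pcs, min(X.shape) - 1)
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(
        X - X.mean(axis=0, keepdims=True)
    )
    k = min(k_neighbors, X.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    a = nn.kneighbors_graph(pcs, mode="connectivity").tolil()
    a.setdiag(0)
    a = ((a + a.T) > 0).tocoo()
    edges = [(int(i), int(j)) for i, j in zip(a.row, a.col) if i < j]
    graph = igraph.Graph(n=X.shape[0], edges=edges)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership, dtype=int)


def find_markers(
    X: pd.DataFrame,
    labels: np.ndarray,
    log2fc_min: float = 0.25,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest cluster markers with a fold-change and p-value gate.

    Returns a table with one row per (cluster, gene): the rank-sum p,
    the log2 fold change of expm1-scale means (cluster vs rest) and
    ``passed = (log2fc >= log2fc_min) & (p < p_max)``. Clusters with
    fewer than 2 spots are skipped with a warning.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValidationError("find_markers requires at least two clusters")
    values = X.to_numpy(dtype=float)
    linear = np.expm1(values)
    rows = []
    for cl in uniq:
        mask = labels == cl
        if mask.sum() < 2 or (~mask).sum() < 2:
            warnings.warn(
                f"cluster {cl!r} has fewer than 2 spots; skipped",
                DegenerateDataWarning,
                stacklevel=2,
            )
            continue
        _, p = rank_sum_matrix(values[mask], values[~mask])
        m_in = linear[mask].mean(axis=0)
        m_out = linear[~mask].mean(axis=0)
        lfc = np.array([log2fc(o, i) for o, i in zip(m_out, m_in)])
        rows.append(
            pd.DataFrame(
                {
                    "cluster": cl,
                    "gene": X.columns,
                    "log2fc": lfc,
                    "p": p,
                    "passed": (lfc >= log2fc_min) & (p < p_max),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
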