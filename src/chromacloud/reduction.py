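"""Dimensionality-reduction tracks that turn user data into a 3D point cloud.

Three entry tracks mirror the kinds of data people want to color:

* ``reduce_highdim`` — any dense entities × features matrix: PCA to 50
  components, then UMAP to 3D.
* ``reduce_single_cell`` — a nonnegative count matrix (genes × cells after
  orientation handling; the *genes* receive colors).  Counts are
  depth-normalised per cell and log-transformed (``log(1 + x·sf/total)``),
  then reduced by an uncentered truncated SVD (the counts are deliberately
  neither centered nor scaled) and embedded with UMAP using 50 neighbors.
* ``reduce_distance`` — a precomputed square distance matrix, embedded
  directly by UMAP with ``metric="precomputed"``.

All tracks are deterministic for a fixed seed (UMAP runs single-threaded
when given a ``random_state``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA, TruncatedSVD

from .geometry import PointCloud3

__all__ = [
    "FeatureMatrix",
    "DistanceMatrix",
    "reduce_highdim",
    "reduce_single_cell",
    "reduce_distance",
    "log_normalize",
]

logger = logging.getLogger(__name__)

MIN_ENTITIES = 5  # UMAP needs at least a handful of neighbors


class TooFewEntitiesError(ValueError):
    """Raised when a track receives fewer rows than an embedding can use."""


@dataclass
class FeatureMatrix:
    """Entities (rows, the objects to be colored) × features, dense or sparse."""

    entity_names: list[str]
    feature_names: list[str]
    values: "np.ndarray | sp.spmatrix"

    def __post_init__(self) -> None:
        self.entity_names = [str(n) for n in self.entity_names]
        self.feature_names = [str(n) for n in self.feature_names]
        n, m = self.values.shape
        if len(self.entity_names) != n or len(self.feature_names) != m:
            raise ValueError("name lengths do not match matrix shape")
        if len(set(self.entity_names)) != n:
            raise ValueError("duplicate entity names")
        dense = self.values.toarray() if sp.issparse(self.values) else self.values
        if not np.all(np.isfinite(dense)):
            raise ValueError("non-finite values in feature matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def transpose(self) -> "FeatureMatrix":
        return FeatureMatrix(
            entity_names=list(self.feature_names),
            feature_names=list(self.entity_names),
            values=self.values.T,
        )

    def dense(self) -> np.ndarray:
        return self.values.toarray() if sp.issparse(self.values) else np.asarray(self.values, float)


@dataclass
class DistanceMatrix:
    """Square, symmetric, nonnegative distances with a zero diagonal."""

    names: list[str]
    values: np.ndarray
    symmetry_tol: float = 1e-8

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.names)
        if self.values.shape != (n, n):
            raise ValueError(f"distance matrix must be {n}×{n}, got {self.values.shape}")
        if len(set(self.names)) != n:
            raise ValueError("duplicate names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if np.any(self.values < 0):
            raise ValueError("negative distances")
        if np.max(np.abs(np.diag(self.values))) > self.symmetry_tol:
            raise ValueError("distance matrix diagonal must be zero")
        if np.max(np.abs(self.values - self.values.T)) > self.symmetry_tol:
            raise ValueError(
                "distance matrix is asymmetric beyond tolerance; "
                "symmetrize it (e.g. average with its transpose) first"
            )

    @classmethod
    def symmetrized(cls, names, values, **kw) -> "DistanceMatrix":
        values = np.asarray(values, dtype=float)
        return cls(names=list(names), values=0.5 * (values + values.T), **kw)


def _umap_3d(data, n_neighbors: int, seed: int, metric: str = "euclidean") -> np.ndarray:
    # deferred import: umap pulls in numba and is slow to load
    import umap

    n = data.shape[0]
    n_neighbors = min(n_neighbors, n - 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap chatters about n_jobs/spectral init
        reducer = umap.UMAP(
            n_components=3,
            n_neighbors=n_neighbors,
            metric=metric,
            random_state=int(seed),
        )
        emb = reducer.fit_transform(data)
    return np.asarray(emb, dtype=float)


def _check_size(n: int) -> None:
    if n < MIN_ENTITIES:
        raise TooFewEntitiesError(
            f"need at least {MIN_ENTITIES} entities for a 3D embedding, got {n}"
        )


def reduce_highdim(
    matrix: FeatureMatrix,
    n_pcs: int = 50,
    n_neighbors: int = 15,
    seed: int = 42,
) -> PointCloud3:
    """High-dimensional track: PCA (up to ``n_pcs`` components) then 3D UMAP."""
    n, m = matrix.shape
    _check_size(n)
    x = matrix.dense()
    if np.allclose(x.var(axis=0), 0.0):
        raise ValueError("feature matrix has zero variance; nothing to embed")
    k = min(n_pcs, n - 1, m)
    if m > 3 or k < m:
        x = PCA(n_components=k, random_state=int(seed)).fit_transform(x)
    coords = _umap_3d(x, n_neighbors=n_neighbors, seed=seed)
    return PointCloud3(list(matrix.entity_names), coords)


def log_normalize(counts, scale_factor: float = 1e4, log_base: float | None = None):
    """Depth-normalise a genes × cells count matrix: log(1 + x·sf/cell_total).

    Natural log by default; pass ``log_base`` (e.g. 2) to change base.
    Cells (columns) with zero total are dropped with a warning.
    """
    dense = counts.toarray() if sp.issparse(counts) else np.asarray(counts, dtype=float)
    if np.any(dense < 0):
        raise ValueError("counts must be nonnegative")
    totals = dense.sum(axis=0)
    keep = totals > 0
    if not np.all(keep):
        logger.warning("dropping %d zero-total cell(s)", int(np.sum(~keep)))
        dense, totals = dense[:, keep], totals[keep]
    out = np.log1p(dense * (scale_factor / totals))
    if log_base is not None:
        out /= np.log(log_base)
    return out, keep


def reduce_single_cell(
    counts: FeatureMatrix,
    scale_factor: float = 1e4,
    n_pcs: int = 50,
    n_neighbors: int = 50,
    seed: int = 42,
    log_base: float | None = None,
    genes_in_rows: bool = True,
) -> PointCloud3:
    """Single-cell track: color the *genes* of a count matrix.

    The matrix is oriented genes × cells (set ``genes_in_rows=False`` for a
    cells × genes input), depth-normalised and log-transformed per cell,
    reduced by uncentered truncated SVD to ``n_pcs`` components — the data
    are deliberately not centered or scaled — and embedded in 3D by UMAP
    with ``n_neighbors`` (default 50) neighbors per gene.
    """
    mat = counts if genes_in_rows else counts.transpose()
    n_genes, _ = mat.shape
    _check_size(n_genes)
    norm, _ = log_normalize(mat.values, scale_factor=scale_factor, log_base=log_base)
    k = min(n_pcs, min(norm.shape) - 1)
    x = TruncatedSVD(n_components=k, random_state=int(seed)).fit_transform(norm)
    coords = _umap_3d(x, n_neighbors=n_neighbors, seed=seed)
    return PointCloud3(list(mat.entity_names), coords)


def reduce_distance(
    dist: DistanceMatrix,
    n_neighbors: int = 15,
    seed: int = 42,
) -> PointCloud3:
    """Distance-matrix track: 3D UMAP on a precomputed metric."""
    _check_size(len(dist.names))
    coords = _umap_3d(dist.values, n_neighbors=n_neighbors, seed=seed, metric="precomputed")
    return PointCloud3(list(dist.names), coords)
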