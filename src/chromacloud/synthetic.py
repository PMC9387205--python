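"""Synthetic datasets with ground-truth group labels, for tests and demos.

Each generator builds a dataset with a known 3-group structure so the
pipeline's headline property — similar profiles receive similar colors —
can be checked against labels the generator controls:

* ``clusters3d`` — three isotropic Gaussian clusters (σ = 1) in 3D whose
  centers sit at mutual distance 10σ: well-separated, directly colorable.
* ``highdim_clusters`` — the same design in 50 dimensions, for the
  PCA + UMAP track.
* ``sc_counts`` — a sparse genes × cells count matrix with three gene
  modules: genes within a module share a cell-loading pattern and counts
  are Poisson draws around it, giving > 50 % zeros at the default means.
* ``cliques_dist`` — a distance matrix of three tight cliques
  (within-clique distance 0.1, between-clique 10).

Generators return in-memory objects; ``write_fixture`` materialises any of
them to plain-text files (CSV/TSV/MatrixMarket) plus a label sidecar.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .geometry import PointCloud3
from .reduction import DistanceMatrix, FeatureMatrix

__all__ = [
    "clusters3d",
    "highdim_clusters",
    "sc_counts",
    "cliques_dist",
    "write_fixture",
    "FIXTURE_KINDS",
]

_N_GROUPS = 3


def _group_labels(n: int) -> np.ndarray:
    """Balanced labels 0..2 (first groups take the remainder)."""
    sizes = [n // _N_GROUPS + (1 if i < n % _N_GROUPS else 0) for i in range(_N_GROUPS)]
    return np.repeat(np.arange(_N_GROUPS), sizes)


def _cluster_centers(dim: int, separation: float) -> np.ndarray:
    """Three centers at mutual distance ``separation``: an equilateral triangle."""
    base = np.zeros((_N_GROUPS, dim))
    base[1, 0] = 1.0
    base[2, 0], base[2, 1] = 0.5, np.sqrt(3) / 2
    return base * separation


def clusters3d(
    n: int = 60, seed: int = 42, sigma: float = 1.0, separation: float = 10.0
) -> tuple[PointCloud3, np.ndarray]:
    """Three Gaussian clusters in 3D; returns (cloud, labels)."""
    rng = np.random.default_rng(seed)
    labels = _group_labels(n)
    centers = _cluster_centers(3, separation * sigma)
    coords = centers[labels] + rng.normal(0.0, sigma, size=(n, 3))
    names = [f"pt{i:04d}" for i in range(n)]
    return PointCloud3(names, coords), labels


def highdim_clusters(
    n: int = 300, dim: int = 50, seed: int = 42, sigma: float = 1.0, separation: float = 10.0
) -> tuple[FeatureMatrix, np.ndarray]:
    """Three Gaussian clusters in ``dim`` dimensions; returns (matrix, labels)."""
    rng = np.random.default_rng(seed)
    labels = _group_labels(n)
    centers = _cluster_centers(dim, separation * sigma)
    values = centers[labels] + rng.normal(0.0, sigma, size=(n, dim))
    return (
        FeatureMatrix(
            entity_names=[f"ent{i:04d}" for i in range(n)],
            feature_names=[f"f{j:03d}" for j in range(dim)],
            values=values,
        ),
        labels,
    )


def sc_counts(
    n_genes: int = 90,
    n_cells: int = 120,
    seed: int = 42,
    module_mean: float = 3.0,
    background_mean: float = 0.05,
) -> tuple[FeatureMatrix, np.ndarray]:
    """Sparse synthetic count matrix with three gene modules.

    Cells are split into three programs; genes of module k are expressed
    (Poisson mean ``module_mean``) in the cells of program k and at a low
    background mean elsewhere, so module-mates share a cell-loading
    pattern.  Returns (genes × cells FeatureMatrix with sparse backing,
    gene module labels).
    """
    rng = np.random.default_rng(seed)
    gene_labels = _group_labels(n_genes)
    cell_programs = _group_labels(n_cells)
    rng.shuffle(cell_programs)
    means = np.where(
        gene_labels[:, None] == cell_programs[None, :], module_mean, background_mean
    )
    counts = rng.poisson(means)
    mat = FeatureMatrix(
        entity_names=[f"gene{i:04d}" for i in range(n_genes)],
        feature_names=[f"cell{j:04d}" for j in range(n_cells)],
        values=sp.csr_matrix(counts),
    )
    return mat, gene_labels


def cliques_dist(
    n: int = 60, seed: int = 42, within: float = 0.1, between: float = 10.0
) -> tuple[DistanceMatrix, np.ndarray]:
    """Distance matrix of three tight cliques; returns (matrix, labels).

    Small seeded jitter (1 % of the within-distance) breaks exact ties so
    the embedding has no degenerate neighbor ordering.
    """
    rng = np.random.default_rng(seed)
    labels = _group_labels(n)
    base = np.where(labels[:, None] == labels[None, :], within, between)
    jitter = rng.uniform(0.0, 0.01 * within, size=(n, n))
    d = base + jitter + jitter.T
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(names=[f"node{i:04d}" for i in range(n)], values=d), labels


FIXTURE_KINDS = ("clusters3d", "highdim-clusters", "sc-counts", "cliques-dist")


def write_fixture(kind: str, n: int, seed: int, out_path) -> list[str]:
    """Write the named dataset kind plus a ``<stem>.labels.tsv`` sidecar.

    ``out_path`` is the main data file; returns all paths written.
    Deterministic: the same kind, n and seed give identical files.
    """
    import os

    from . import io as cio

    if n < 12:
        raise ValueError("fixtures need n >= 12 (balanced groups, enough neighbors)")
    out_path = str(out_path)
    stem, _ = os.path.splitext(out_path)
    written = [out_path]

    if kind == "clusters3d":
        cloud, labels = clusters3d(n=n, seed=seed)
        cio.write_cloud3d(cloud, out_path)
        names = cloud.names
    elif kind == "highdim-clusters":
        mat, labels = highdim_clusters(n=n, seed=seed)
        cio.write_feature_matrix(mat, out_path)
        names = mat.entity_names
    elif kind == "sc-counts":
        mat, labels = sc_counts(n_genes=n, seed=seed)
        written = cio.write_sparse_counts(mat, out_path)
        names = mat.entity_names
    elif kind == "cliques-dist":
        dist, labels = cliques_dist(n=n, seed=seed)
        cio.write_distance_matrix(dist, out_path)
        names = dist.names
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")

    label_path = stem + ".labels.tsv"
    with open(label_path, "w") as fh:
        fh.write("name\tlabel\n")
        for name, lab in zip(names, labels):
            fh.write(f"{name}\t{lab}\n")
    written.append(label_path)
    return written
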