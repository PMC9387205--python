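"""File I/O for every track, and the end-to-end pipeline runner.

Dense matrices and 3D data travel as CSV/TSV with a header row and an
entity-name first column; sparse counts travel as Matrix Market (.mtx)
with ``<stem>.rows.txt`` / ``<stem>.cols.txt`` sidecar name files.  Fit
results travel as JSON.  All outputs are written atomically (temp file in
the target directory, then rename) so a failing run never leaves a
partial table behind.
"""

from __future__ import annotations

import logging
import os
import tempfile
import time
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .fitting import AxisWeights, FitConfig, FitResult, encode, fit_cloud
from .gamut import GamutModel
from .geometry import PointCloud3
from .reduction import (
    DistanceMatrix,
    FeatureMatrix,
    reduce_distance,
    reduce_highdim,
    reduce_single_cell,
)
from .table import ColorTable

__all__ = [
    "read_cloud3d",
    "write_cloud3d",
    "read_feature_matrix",
    "write_feature_matrix",
    "read_sparse_counts",
    "write_sparse_counts",
    "read_distance_matrix",
    "write_distance_matrix",
    "run_track",
    "TRACKS",
]

logger = logging.getLogger(__name__)

TRACKS = ("single-cell", "highdim", "distmatrix", "direct3d")


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def _read_table(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    except Exception as exc:  # pandas errors carry line info; add the file name
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no data columns found after the name column")
    return df


def _atomic_write(path, write_fn) -> None:
    """Write via a temp file in the same directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name, suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# -- 3D clouds -------------------------------------------------------------


def read_cloud3d(path) -> PointCloud3:
    df = _read_table(path)
    if df.shape[1] != 3:
        raise ValueError(f"{path}: direct-3D input needs exactly 3 coordinate columns, got {df.shape[1]}")
    return PointCloud3([str(i) for i in df.index], df.to_numpy(dtype=float))


def write_cloud3d(cloud: PointCloud3, path) -> None:
    df = pd.DataFrame(cloud.coords, index=cloud.names, columns=["x", "y", "z"])
    _atomic_write(path, lambda p: df.to_csv(p, sep=_sep_for(path), index_label="name"))


# -- dense feature matrices --------------------------------------------------


def read_feature_matrix(path, transpose: bool = False) -> FeatureMatrix:
    df = _read_table(path)
    mat = FeatureMatrix(
        entity_names=[str(i) for i in df.index],
        feature_names=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )
    return mat.transpose() if transpose else mat


def write_feature_matrix(mat: FeatureMatrix, path) -> None:
    df = pd.DataFrame(mat.dense(), index=mat.entity_names, columns=mat.feature_names)
    _atomic_write(path, lambda p: df.to_csv(p, sep=_sep_for(path), index_label="name"))


# -- sparse counts (Matrix Market + name sidecars) ---------------------------


def _sidecar_paths(path) -> tuple[str, str]:
    stem = os.path.splitext(str(path))[0]
    return stem + ".rows.txt", stem + ".cols.txt"


def read_sparse_counts(path, transpose: bool = False) -> FeatureMatrix:
    rows_path, cols_path = _sidecar_paths(path)
    for p in (rows_path, cols_path):
        if not os.path.exists(p):
            raise ValueError(f"missing sidecar name file {p} for {path}")
    values = sp.csr_matrix(sio.mmread(path))
    rows = Path(rows_path).read_text().split()
    cols = Path(cols_path).read_text().split()
    mat = FeatureMatrix(entity_names=rows, feature_names=cols, values=values)
    return mat.transpose() if transpose else mat


def write_sparse_counts(mat: FeatureMatrix, path) -> list[str]:
    rows_path, cols_path = _sidecar_paths(path)
    values = sp.coo_matrix(mat.values)

    def _write(p):
        with open(p, "wb") as fh:  # file handle: keeps mmwrite from renaming
            sio.mmwrite(fh, values)

    _atomic_write(path, _write)
    Path(rows_path).write_text("\n".join(mat.entity_names) + "\n")
    Path(cols_path).write_text("\n".join(mat.feature_names) + "\n")
    return [str(path), rows_path, cols_path]


# -- distance matrices -------------------------------------------------------


def read_distance_matrix(path, symmetrize: bool = False) -> DistanceMatrix:
    df = _read_table(path)
    if df.shape[0] != df.shape[1]:
        raise ValueError(
            f"{path}: distance matrix must be square, got {df.shape[0]}×{df.shape[1]}"
        )
    names = [str(i) for i in df.index]
    values = df.to_numpy(dtype=float)
    if symmetrize:
        return DistanceMatrix.symmetrized(names, values)
    return DistanceMatrix(names=names, values=values)


def write_distance_matrix(dist: DistanceMatrix, path) -> None:
    df = pd.DataFrame(dist.values, index=dist.names, columns=dist.names)
    _atomic_write(path, lambda p: df.to_csv(p, sep=_sep_for(path), index_label="name"))


# -- pipeline runner ---------------------------------------------------------


def run_track(
    track: str,
    input_path,
    output_path,
    weights: AxisWeights | None = None,
    config: FitConfig | None = None,
    format: str = "both",
    clamp: bool = True,
    transpose: bool = False,
    save_fit_path=None,
    apply_fit_path=None,
    n_neighbors: int | None = None,
    seed: int | None = None,
) -> tuple[ColorTable, FitResult]:
    """Run a full track: read → reduce (unless direct3d) → fit → encode → write.

    Writes the color table as TSV to ``output_path`` and, if requested, the
    fit as JSON to ``save_fit_path``.  With ``apply_fit_path`` the
    optimisation is skipped and a stored transform is reapplied (the input
    must be 3D data in the frame of the original fit).  Returns the
    in-memory (ColorTable, FitResult).
    """
    if track not in TRACKS:
        raise ValueError(f"unknown track {track!r}; choose from {TRACKS}")
    config = config or FitConfig()
    if seed is not None:
        config.seed = seed
    seed = config.seed
    gamut = GamutModel()

    t0 = time.perf_counter()
    if track == "direct3d":
        cloud = read_cloud3d(input_path)
    elif track == "highdim":
        mat = read_feature_matrix(input_path, transpose=transpose)
        kw = {"n_neighbors": n_neighbors} if n_neighbors else {}
        cloud = reduce_highdim(mat, seed=seed, **kw)
    elif track == "single-cell":
        mat = read_sparse_counts(input_path, transpose=transpose)
        kw = {"n_neighbors": n_neighbors} if n_neighbors else {}
        cloud = reduce_single_cell(mat, seed=seed, **kw)
    else:  # distmatrix
        dist = read_distance_matrix(input_path)
        kw = {"n_neighbors": n_neighbors} if n_neighbors else {}
        cloud = reduce_distance(dist, seed=seed, **kw)
    logger.info("reduction: %d points in %.2fs", len(cloud), time.perf_counter() - t0)

    t1 = time.perf_counter()
    if apply_fit_path is not None:
        result = FitResult.from_json(apply_fit_path)
        logger.info("loaded stored fit from %s", apply_fit_path)
    else:
        result = fit_cloud(cloud, weights=weights, config=config, gamut=gamut)
        logger.info(
            "fit: objective %.3f, scale %.2f in %.2fs",
            result.objective, result.best.scale, time.perf_counter() - t1,
        )

    table = encode(cloud, result, gamut=gamut, format=format, clamp=clamp)
    if table.n_clamped:
        logger.info("%d point(s) clamped into the gamut", table.n_clamped)

    _atomic_write(output_path, lambda p: table.to_tsv(p))
    if save_fit_path is not None:
        _atomic_write(save_fit_path, lambda p: result.to_json(p))
    logger.info("wrote %s (%d rows)", output_path, len(table))
    return table, result
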