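"""Named 3D point clouds, convex-hull extraction and similarity transforms."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError

__all__ = ["PointCloud3", "TransformParams", "convex_hull", "apply_transform"]


@dataclass
class PointCloud3:
    """A set of named points in 3D (post-fit, the axes are L*, a*, b*).

    Invariants: at least one point, unique names, finite coordinates.
    Duplicate *coordinates* are allowed — distinct entities may land on the
    same position after dimensionality reduction.
    """

    names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.names = [str(n) for n in self.names]
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be N×3, got shape {self.coords.shape}")
        if len(self.coords) < 1:
            raise ValueError("point cloud must contain at least one point")
        if len(self.names) != len(self.coords):
            raise ValueError("names and coords lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("duplicate entity names in point cloud")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in point cloud")

    def __len__(self) -> int:
        return len(self.coords)

    def subset(self, indices: Sequence[int]) -> "PointCloud3":
        idx = list(indices)
        return PointCloud3([self.names[i] for i in idx], self.coords[idx])


@dataclass
class TransformParams:
    """The 7 fit parameters: translation, Euler angles, uniform scale.

    Rotation angles are applied intrinsically about the L*, a*, b* axes in
    that fixed order: R = R_b(θ3) · R_a(θ2) · R_L(θ1).  Angles are radians
    and are not normalised to any range; scale must be positive.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3)
        self.scale = float(self.scale)
        if not (np.all(np.isfinite(self.translation)) and np.all(np.isfinite(self.rotation))):
            raise ValueError("non-finite transform parameters")
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    def rotation_matrix(self) -> np.ndarray:
        t1, t2, t3 = self.rotation
        c, s = np.cos, np.sin
        rl = np.array([[1, 0, 0], [0, c(t1), -s(t1)], [0, s(t1), c(t1)]])
        ra = np.array([[c(t2), 0, s(t2)], [0, 1, 0], [-s(t2), 0, c(t2)]])
        rb = np.array([[c(t3), -s(t3), 0], [s(t3), c(t3), 0], [0, 0, 1]])
        return rb @ ra @ rl

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.translation, self.rotation, [self.scale]])

    @classmethod
    def from_vector(cls, v) -> "TransformParams":
        v = np.asarray(v, dtype=float)
        return cls(translation=v[:3], rotation=v[3:6], scale=v[6])


def convex_hull(cloud: PointCloud3) -> PointCloud3:
    """Points of the cloud that are vertices of its 3D convex hull.

    Degenerate inputs (N ≤ 4, collinear/coplanar clouds) return all points
    with distinct coordinates.  Names are preserved; where several entities
    share a hull-vertex coordinate, the first occurrence represents it.
    """
    coords, first_idx = np.unique(cloud.coords, axis=0, return_index=True)
    if len(coords) <= 4:
        return cloud.subset(sorted(first_idx))
    try:
        hull = ConvexHull(coords)
    except QhullError:
        # coplanar or collinear cloud: every distinct point may bound it
        return cloud.subset(sorted(first_idx))
    return cloud.subset(sorted(first_idx[hull.vertices]))


def apply_transform(cloud: PointCloud3, params: TransformParams) -> PointCloud3:
    """Similarity transform x ↦ s·R(θ)·x + t; names and order unchanged."""
    new = transform_coords(cloud.coords, params)
    return PointCloud3(list(cloud.names), new)


def transform_coords(coords: np.ndarray, params: TransformParams) -> np.ndarray:
    """Apply the similarity transform to a raw (N, 3) coordinate array."""
    rot = params.rotation_matrix()
    return params.scale * np.asarray(coords, dtype=float) @ rot.T + params.translation
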