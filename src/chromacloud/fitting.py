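"""Fitting a 3D point cloud inside the displayable CIELAB gamut.

The core optimisation: find the translation, rotation and uniform scale
that make the cloud as large as possible while keeping it inside the
region of CIELAB that an sRGB monitor can display.  Only the convex-hull
vertices of the cloud enter the objective — under a similarity transform
the hull bounds the whole cloud, which makes the fit cost independent of
the number of input points.

Objective (maximised):

    size(T(hull)) − λ · mean_vertex_overshoot(T(hull))

where size is the axis-weighted mean of the per-axis extents of the
transformed hull, ``size = (wL·extL + wa·exta + wb·extb) / (wL+wa+wb)``,
and overshoot is the CIELAB distance by which a vertex protrudes past the
gamut boundary.  The cloud is normalised (centroid at the origin, maximum
radius 1) before fitting, so λ has a scale-free meaning and the recorded
transform can be reapplied to new data in the same coordinate frame.

Because the objective is non-convex in the rotation angles, Nelder–Mead is
restarted from 25 initial rotations (identity plus 24 seeded uniform random
ones); all solutions are returned, ranked, so alternative color schemes can
be inspected.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .colorspace import OutOfGamutError, lab_to_hex
from .gamut import GamutModel
from .geometry import PointCloud3, TransformParams, apply_transform, convex_hull, transform_coords
from .table import ColorTable

__all__ = ["AxisWeights", "FitConfig", "FitResult", "objective", "fit_cloud", "encode"]

logger = logging.getLogger(__name__)

_INITIAL_SCALE = 40.0  # comfortably inside the gamut for a unit-radius cloud

# initial simplex edge per parameter block: the scipy default (5% of x0)
# collapses for rotation angles near 0 and stalls the search in shallow
# basins; edges must match each parameter's natural scale instead
_SIMPLEX_STEPS = np.array([10.0, 10.0, 10.0, 0.6, 0.6, 0.6, 10.0])

_MAX_POLISH_ROUNDS = 10  # simplex restarts from the incumbent best


@dataclass
class AxisWeights:
    """Relative priority of spreading the cloud along L*, a*, b*."""

    wL: float = 1.0
    wa: float = 1.0
    wb: float = 1.0

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("axis weights must be nonnegative with at least one positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.wL, self.wa, self.wb], dtype=float)


@dataclass
class FitConfig:
    """Optimisation settings.

    ``n_starts`` Nelder–Mead restarts from different initial rotations;
    ``penalty_lambda`` weights the *mean* hull-vertex overshoot against the
    cloud size.  Because the penalty averages over hull vertices, the
    marginal cost of letting one vertex protrude is λ / n_vertices, while
    growing the cloud gains up to ~2 size units per scale unit; λ must
    therefore exceed ~2·n_vertices for the optimum to keep every vertex
    inside.  The default of 1000 guarantees containment for hulls of up to
    several hundred vertices — far more than 3D clouds produce in practice.
    """

    n_starts: int = 25
    penalty_lambda: float = 1000.0
    seed: int = 42
    max_iter_per_start: int = 2000
    xatol: float = 1e-6
    fatol: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.penalty_lambda <= 0:
            raise ValueError("penalty_lambda must be positive")
        if self.xatol <= 0 or self.fatol <= 0:
            raise ValueError("convergence tolerances must be positive")


@dataclass
class FitResult:
    """Best transform plus the full ranked multi-start solution table."""

    best: TransformParams
    objective: float
    normalization: tuple[np.ndarray, float]  # (centroid, radius) of the input cloud
    alternatives: list[tuple[TransformParams, float]] = field(default_factory=list)

    def normalize_coords(self, coords: np.ndarray) -> np.ndarray:
        centroid, radius = self.normalization
        return (np.asarray(coords, dtype=float) - centroid) / radius

    # -- JSON round trip so a fit can be saved and reapplied ---------------

    def to_json(self, path=None) -> str:
        def enc(p: TransformParams, obj: float) -> dict:
            return {
                "translation": p.translation.tolist(),
                "rotation": p.rotation.tolist(),
                "scale": p.scale,
                "objective": obj,
            }

        payload = {
            "best": enc(self.best, self.objective),
            "normalization": {
                "centroid": np.asarray(self.normalization[0]).tolist(),
                "radius": float(self.normalization[1]),
            },
            "alternatives": [enc(p, o) for p, o in self.alternatives],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)

        def dec(d: dict) -> tuple[TransformParams, float]:
            return (
                TransformParams(
                    translation=d["translation"], rotation=d["rotation"], scale=d["scale"]
                ),
                float(d["objective"]),
            )

        best, obj = dec(payload["best"])
        norm = payload["normalization"]
        alts = [dec(d) for d in payload.get("alternatives", [])]
        return cls(
            best=best,
            objective=obj,
            normalization=(np.asarray(norm["centroid"], dtype=float), float(norm["radius"])),
            alternatives=alts,
        )


def objective(
    params: TransformParams,
    hull: PointCloud3,
    weights: AxisWeights,
    config: FitConfig,
    gamut: GamutModel,
) -> float:
    """Axis-weighted size of the transformed hull minus the overshoot penalty.

    Expects ``hull`` to be the convex-hull cloud of a normalised input
    (centroid 0, max radius 1), which is what :func:`fit_cloud` evaluates.
    """
    t = transform_coords(hull.coords, params)
    w = weights.as_array()
    extents = t.max(axis=0) - t.min(axis=0)
    size = float(w @ extents) / float(w.sum())
    mean_over = float(np.mean(gamut.overshoot(t)))
    return size - config.penalty_lambda * mean_over


def _normalize(cloud: PointCloud3) -> tuple[np.ndarray, np.ndarray, float]:
    centroid = cloud.coords.mean(axis=0)
    centered = cloud.coords - centroid
    radius = float(np.max(np.linalg.norm(centered, axis=1)))
    if radius == 0.0:
        radius = 1.0  # single point / fully degenerate cloud
    return centered / radius, centroid, radius


def fit_cloud(
    cloud: PointCloud3,
    weights: AxisWeights | None = None,
    config: FitConfig | None = None,
    gamut: GamutModel | None = None,
) -> FitResult:
    """Multi-start Nelder–Mead fit of a point cloud into the CIELAB gamut.

    The cloud is normalised to centroid 0 / max radius 1 (recorded in the
    result so the transform can be reapplied to new points in the original
    frame), its convex hull is extracted, and ``config.n_starts`` simplex
    runs maximise the size-minus-penalty objective.  Start 0 begins at the
    identity rotation; the rest draw rotation angles uniformly from
    [0, 2π)³ using a generator seeded with ``config.seed``.  Every start
    begins translated to the gamut's interior point at scale 40.
    Deterministic for a fixed seed; ties between starts go to the lowest
    start index.
    """
    weights = weights or AxisWeights()
    config = config or FitConfig()
    gamut = gamut or GamutModel()
    if len(cloud) == 0:
        raise ValueError("cannot fit an empty point cloud")

    norm_coords, centroid, radius = _normalize(cloud)
    hull = convex_hull(PointCloud3(list(cloud.names), norm_coords))
    hull_coords = hull.coords
    w = weights.as_array()
    wsum = float(w.sum())
    lam = config.penalty_lambda

    def neg_objective(v: np.ndarray) -> float:
        if v[6] <= 0 or not np.all(np.isfinite(v)):
            return 1e9  # outside the valid parameter domain
        params = TransformParams(translation=v[:3], rotation=v[3:6], scale=v[6])
        t = transform_coords(hull_coords, params)
        extents = t.max(axis=0) - t.min(axis=0)
        size = float(w @ extents) / wsum
        mean_over = float(np.mean(gamut.overshoot(t)))
        return -(size - lam * mean_over)

    rng = np.random.default_rng(config.seed)
    init_rotations = rng.uniform(0.0, 2 * np.pi, size=(config.n_starts, 3))
    init_rotations[0] = 0.0  # start 0: identity rotation

    solutions: list[tuple[TransformParams, float]] = []
    for i in range(config.n_starts):
        x0 = np.concatenate([gamut.interior_point, init_rotations[i], [_INITIAL_SCALE]])
        res = minimize(
            neg_objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter_per_start,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "initial_simplex": np.vstack([x0, x0 + np.diag(_SIMPLEX_STEPS)]),
            },
        )
        params = TransformParams.from_vector(res.x)
        solutions.append((params, float(-res.fun)))
        logger.debug("start %d: objective %.4f (scale %.2f)", i, -res.fun, params.scale)

    # rank descending; stable sort keeps the lowest start index on ties
    order = sorted(range(len(solutions)), key=lambda i: -solutions[i][1])
    ranked = [solutions[i] for i in order]
    best, best_obj = ranked[0]

    # polish: restart the simplex from the incumbent best until it stops
    # improving — the re-expanded initial simplex can escape the shallow
    # basins where a single Nelder-Mead run stalls
    x, obj = best.to_vector(), best_obj
    for r in range(_MAX_POLISH_ROUNDS):
        res = minimize(
            neg_objective,
            x,
            method="Nelder-Mead",
            options={
                "maxiter": config.max_iter_per_start,
                "xatol": config.xatol,
                "fatol": config.fatol,
                "initial_simplex": np.vstack([x, x + np.diag(_SIMPLEX_STEPS)]),
            },
        )
        if -res.fun <= obj + config.fatol:
            break
        x, obj = res.x, float(-res.fun)
    if obj > best_obj:
        logger.debug("polish improved objective %.4f -> %.4f in %d rounds", best_obj, obj, r)
        best, best_obj = TransformParams.from_vector(x), obj
        ranked[0] = (best, best_obj)

    return FitResult(
        best=best,
        objective=best_obj,
        normalization=(centroid, radius),
        alternatives=ranked,
    )


def encode(
    cloud: PointCloud3,
    result: FitResult,
    gamut: GamutModel | None = None,
    format: str = "both",
    clamp: bool = True,
) -> ColorTable:
    """Assign a color to every point using a previously fitted transform.

    ``cloud`` may be the fitted cloud itself or new points in the same
    coordinate frame: the stored normalisation and best transform are
    applied, then CIELAB coordinates are converted to hex.  Points that
    land outside the gamut (possible for interior/new points, since the
    gamut is not convex) are clamped in RGB when ``clamp`` is true and
    counted; with ``clamp`` false they raise, naming the offenders.
    """
    if format not in ("hex", "lab", "both"):
        raise ValueError(f"unknown format {format!r}")
    gamut = gamut or GamutModel()
    lab = transform_coords(result.normalize_coords(cloud.coords), result.best)
    inside = np.atleast_1d(gamut.contains(lab))
    n_out = int(np.sum(~inside))
    if n_out and not clamp:
        offenders = [cloud.names[i] for i in np.flatnonzero(~inside)]
        raise OutOfGamutError(
            f"{n_out} point(s) fall outside the displayable gamut: "
            + ", ".join(offenders[:10])
            + ("..." if n_out > 10 else "")
        )
    if n_out:
        logger.warning("%d point(s) outside the gamut were clamped in RGB", n_out)
    hexes = lab_to_hex(lab, clamp=True)  # lab is always (N, 3) here → list
    return ColorTable(
        names=list(cloud.names), lab=lab, hex=list(hexes),
        n_clamped=n_out, format=format,
    )


def fit_and_encode(
    cloud: PointCloud3,
    weights: AxisWeights | None = None,
    config: FitConfig | None = None,
    gamut: GamutModel | None = None,
    format: str = "both",
    clamp: bool = True,
) -> tuple[ColorTable, FitResult]:
    """Convenience wrapper: fit the cloud, then color it."""
    gamut = gamut or GamutModel()
    result = fit_cloud(cloud, weights=weights, config=config, gamut=gamut)
    table = encode(cloud, result, gamut=gamut, format=format, clamp=clamp)
    return table, result
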