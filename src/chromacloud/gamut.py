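"""The displayable region of CIELAB: the image of the sRGB unit cube.

Membership is decided analytically by inverting the color transform — the
gamut is exactly the preimage of the unit RGB cube, so no mesh test is
needed.  The overshoot distance used as the fit penalty is measured along
the ray from a fixed interior point (mid-gray) to the query point: a
bisection locates the boundary crossing, and the overshoot is the Euclidean
CIELAB distance from the crossing to the query.  This is cheap,
deterministic and continuous, which is all the penalty needs; it is not the
true nearest-boundary distance on the (slightly non-convex) gamut surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorspace import lab_to_srgb, srgb_to_lab

__all__ = ["GamutModel", "in_gamut", "overshoot"]

_RGB_TOL = 1e-9


def _mid_gray_lab() -> np.ndarray:
    return srgb_to_lab(np.array([0.5, 0.5, 0.5]))


@dataclass
class GamutModel:
    """Displayable CIELAB region with membership and overshoot queries.

    Parameters
    ----------
    interior_point : (3,) Lab coordinates guaranteed inside the gamut;
        defaults to the image of sRGB (0.5, 0.5, 0.5).
    tolerance : membership tolerance in RGB units.
    mesh_resolution : per-face sampling density for the optional boundary
        mesh (visualization only; never used for membership).
    """

    interior_point: np.ndarray = field(default_factory=_mid_gray_lab)
    tolerance: float = _RGB_TOL
    mesh_resolution: int = 16

    def __post_init__(self) -> None:
        self.interior_point = np.asarray(self.interior_point, dtype=float)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not self.contains(self.interior_point):
            raise ValueError("interior_point is not inside the gamut")

    # -- membership ------------------------------------------------------

    def contains(self, lab) -> "bool | np.ndarray":
        """True where the Lab color(s) are displayable in sRGB."""
        rgb = np.asarray(lab_to_srgb(lab))
        ok = np.all((rgb >= -self.tolerance) & (rgb <= 1 + self.tolerance), axis=-1)
        return bool(ok) if np.isscalar(ok) or ok.ndim == 0 else ok

    # -- overshoot -------------------------------------------------------

    def overshoot(self, lab, n_bisect: int = 48) -> "float | np.ndarray":
        """Distance (CIELAB units) by which color(s) protrude past the gamut.

        Zero for in-gamut points.  For an outside point p, a bisection with
        ``n_bisect`` steps (>= 40, giving < 1e-6 relative precision) finds
        the boundary crossing on the segment interior_point → p, and the
        overshoot is |p - crossing|.
        """
        arr = np.atleast_2d(np.asarray(lab, dtype=float))
        single = np.asarray(lab).ndim == 1
        inside = np.atleast_1d(self.contains(arr))
        out = np.zeros(len(arr))
        if not np.all(inside):
            idx = np.flatnonzero(~inside)
            p = arr[idx]
            c = self.interior_point
            lo = np.zeros(len(idx))  # inside end of bracket (fraction of segment)
            hi = np.ones(len(idx))  # outside end
            for _ in range(max(n_bisect, 40)):
                mid = 0.5 * (lo + hi)
                mid_in = np.atleast_1d(self.contains(c + mid[:, None] * (p - c)))
                lo = np.where(mid_in, mid, lo)
                hi = np.where(mid_in, hi, mid)
            t = 0.5 * (lo + hi)
            out[idx] = (1.0 - t) * np.linalg.norm(p - c, axis=1)
        return float(out[0]) if single else out

    # -- visualization mesh ----------------------------------------------

    def boundary_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """Triangulated gamut surface: Lab images of the RGB cube faces.

        Returns (vertices, faces) where vertices is (V, 3) Lab and faces is
        (F, 3) integer indices.  Intended for inspection/plotting only.
        """
        k = self.mesh_resolution
        u = np.linspace(0.0, 1.0, k + 1)
        uu, vv = np.meshgrid(u, u, indexing="ij")
        verts, faces = [], []
        offset = 0
        for axis in range(3):
            for level in (0.0, 1.0):
                face_rgb = np.zeros((uu.size, 3))
                others = [a for a in range(3) if a != axis]
                face_rgb[:, axis] = level
                face_rgb[:, others[0]] = uu.ravel()
                face_rgb[:, others[1]] = vv.ravel()
                verts.append(srgb_to_lab(face_rgb))
                n = k + 1
                for i in range(k):
                    for j in range(k):
                        a = offset + i * n + j
                        faces.append([a, a + 1, a + n])
                        faces.append([a + 1, a + n + 1, a + n])
                offset += uu.size
        return np.vstack(verts), np.asarray(faces, dtype=int)

    def export_mesh_obj(self, path) -> None:
        """Write the boundary mesh as a Wavefront OBJ file."""
        verts, faces = self.boundary_mesh()
        with open(path, "w") as fh:
            for v in verts:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def in_gamut(lab, gamut: GamutModel | None = None):
    """Module-level convenience wrapper for :meth:`GamutModel.contains`."""
    return (gamut or GamutModel()).contains(lab)


def overshoot(lab, gamut: GamutModel | None = None):
    """Module-level convenience wrapper for :meth:`GamutModel.overshoot`."""
    return (gamut or GamutModel()).overshoot(lab)
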