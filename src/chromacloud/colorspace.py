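"""Exact, invertible sRGB ↔ CIE XYZ ↔ CIELAB conversions under D65.

The sRGB→XYZ matrix is derived at import time from the IEC 61966-2-1
primary chromaticities and the D65 white point, so that the neutral axis
(r = g = b) maps exactly onto the CIELAB lightness axis (a* = b* = 0) and
the reference white maps exactly to L* = 100.  Hard-coding the commonly
quoted 7-digit matrix would leave the white point off by ~0.014 CIELAB
units, which matters for gamut geometry.

All conversions are vectorised: functions accept either a single color
(shape ``(3,)``) or an array of colors (shape ``(N, 3)``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "D65_WHITE",
    "SRGB_TO_XYZ",
    "XYZ_TO_SRGB",
    "srgb_to_lab",
    "lab_to_srgb",
    "lab_to_hex",
    "OutOfGamutError",
]


class OutOfGamutError(ValueError):
    """Raised when a CIELAB color outside the sRGB gamut must be displayed."""


def _srgb_matrix() -> np.ndarray:
    """Solve for the sRGB→XYZ matrix from primaries and D65 white.

    Columns are the XYZ coordinates of the red, green and blue primaries,
    scaled so that (1, 1, 1) maps exactly to the D65 white point.
    """
    # IEC 61966-2-1 primary chromaticities (x, y)
    xy = np.array([[0.64, 0.33], [0.30, 0.60], [0.15, 0.06]])
    white = np.array([0.95047, 1.0, 1.08883])  # D65, 2° observer, Y = 1
    # XYZ of each primary up to scale: (x/y, 1, (1-x-y)/y)
    P = np.stack(
        [xy[:, 0] / xy[:, 1], np.ones(3), (1 - xy[:, 0] - xy[:, 1]) / xy[:, 1]],
        axis=0,
    )
    scale = np.linalg.solve(P, white)
    return P * scale


SRGB_TO_XYZ = _srgb_matrix()
XYZ_TO_SRGB = np.linalg.inv(SRGB_TO_XYZ)

#: Reference white on the Y = 100 scale (Xn, Yn, Zn).
D65_WHITE = np.array([95.047, 100.0, 108.883])

_DELTA = 6.0 / 29.0  # CIELAB f(t) linear-branch threshold parameter


def _check_finite(arr: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"non-finite {what} components: {arr!r}")


def _as_colors(c, what: str) -> tuple[np.ndarray, bool]:
    arr = np.asarray(c, dtype=float)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[-1] != 3:
        raise ValueError(f"{what} must have 3 components, got shape {arr.shape}")
    _check_finite(arr, what)
    return arr, single


def _srgb_decode(v: np.ndarray) -> np.ndarray:
    """Nonlinear sRGB → linear light (IEC 61966-2-1 piecewise curve)."""
    v = np.asarray(v, dtype=float)
    sign = np.sign(v)
    v = np.abs(v)  # extend oddly so the inverse is defined for overshoots
    lin = np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)
    return sign * lin


def _srgb_encode(v: np.ndarray) -> np.ndarray:
    """Linear light → nonlinear sRGB."""
    v = np.asarray(v, dtype=float)
    sign = np.sign(v)
    v = np.abs(v)
    enc = np.where(v <= 0.0031308, v * 12.92, 1.055 * v ** (1 / 2.4) - 0.055)
    return sign * enc


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inv(u: np.ndarray) -> np.ndarray:
    return np.where(u > _DELTA, u**3, 3 * _DELTA**2 * (u - 4.0 / 29.0))


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert gamma-encoded sRGB (components in [0, 1]) to CIELAB.

    Parameters
    ----------
    rgb : array-like, shape (3,) or (N, 3)
        Nonlinear sRGB components.  Values outside [0, 1] are converted
        with the oddly-extended transfer function (used by the inverse
        mapping); displayable colors are those inside the unit cube.

    Returns
    -------
    ndarray with the same leading shape: (L*, a*, b*) triples, L* in
    [0, 100] for in-gamut input.
    """
    arr, single = _as_colors(rgb, "RGB")
    xyz = 100.0 * _srgb_decode(arr) @ SRGB_TO_XYZ.T
    f = _lab_f(xyz / D65_WHITE)
    lab = np.empty_like(f)
    lab[:, 0] = 116.0 * f[:, 1] - 16.0
    lab[:, 1] = 500.0 * (f[:, 0] - f[:, 1])
    lab[:, 2] = 200.0 * (f[:, 1] - f[:, 2])
    return lab[0] if single else lab


def lab_to_srgb(lab) -> np.ndarray:
    """Convert CIELAB to gamma-encoded sRGB.

    Exact inverse of :func:`srgb_to_lab` on its range.  Out-of-gamut Lab
    input yields components outside [0, 1]; no clamping is performed here.
    """
    arr, single = _as_colors(lab, "Lab")
    fy = (arr[:, 0] + 16.0) / 116.0
    f = np.stack([fy + arr[:, 1] / 500.0, fy, fy - arr[:, 2] / 200.0], axis=1)
    xyz = _lab_f_inv(f) * D65_WHITE
    rgb = _srgb_encode(xyz / 100.0 @ XYZ_TO_SRGB.T)
    return rgb[0] if single else rgb


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def lab_to_hex(lab, clamp: bool = False) -> "str | list[str]":
    """Format CIELAB color(s) as uppercase ``#RRGGBB`` hex strings.

    Channels are quantised as round(255·c) with half-away-from-zero
    rounding so output is bit-reproducible across platforms.

    Parameters
    ----------
    lab : array-like, shape (3,) or (N, 3)
    clamp : bool
        If True, RGB components are clamped to [0, 1] before quantising.
        If False, out-of-gamut input raises :class:`OutOfGamutError`.
    """
    arr, single = _as_colors(lab, "Lab")
    rgb = np.atleast_2d(lab_to_srgb(arr))
    if clamp:
        rgb = np.clip(rgb, 0.0, 1.0)
    else:
        bad = np.any((rgb < -1e-9) | (rgb > 1 + 1e-9), axis=1)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise OutOfGamutError(
                f"Lab color {tuple(arr[i])} is outside the sRGB gamut "
                f"(rgb={tuple(rgb[i])}); pass clamp=True to clip"
            )
        rgb = np.clip(rgb, 0.0, 1.0)
    q = _round_half_away(rgb * 255.0).astype(int)
    out = [f"#{r:02X}{g:02X}{b:02X}" for r, g, b in q]
    return out[0] if single else out
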