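"""Per-entity color table: the tool's primary output."""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ColorTable"]

_HEX_RE = re.compile(r"^#[0-9A-F]{6}$")


@dataclass
class ColorTable:
    """Rows of (name, L*, a*, b*, hex).

    ``lab`` holds the pre-clamp CIELAB coordinates (so pairwise Lab
    distances remain an exact multiple of the input distances); ``hex``
    holds the displayable color after any RGB clamping.  ``n_clamped``
    counts entities whose color had to be clipped into the sRGB gamut.
    """

    names: list[str]
    lab: np.ndarray
    hex: list[str]
    n_clamped: int = 0
    format: str = "both"  # hex | lab | both

    def __post_init__(self) -> None:
        self.lab = np.asarray(self.lab, dtype=float)
        if len(self.names) != len(self.lab) or len(self.names) != len(self.hex):
            raise ValueError("column lengths differ")
        for h in self.hex:
            if not _HEX_RE.match(h):
                raise ValueError(f"malformed hex code {h!r}")

    def __len__(self) -> int:
        return len(self.names)

    def to_frame(self) -> pd.DataFrame:
        cols: dict = {"name": self.names}
        if self.format in ("lab", "both"):
            cols["L"] = self.lab[:, 0]
            cols["a"] = self.lab[:, 1]
            cols["b"] = self.lab[:, 2]
        if self.format in ("hex", "both"):
            cols["hex"] = self.hex
        return pd.DataFrame(cols)

    def to_tsv(self, path) -> None:
        # full float precision so the written table round-trips exactly
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_tsv(cls, path) -> "ColorTable":
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        names = [str(n) for n in df["name"]]
        has_lab = {"L", "a", "b"} <= set(df.columns)
        has_hex = "hex" in df.columns
        lab = df[["L", "a", "b"]].to_numpy() if has_lab else np.zeros((len(df), 3))
        hexes = list(df["hex"]) if has_hex else ["#000000"] * len(df)
        fmt = "both" if (has_lab and has_hex) else ("lab" if has_lab else "hex")
        return cls(names=names, lab=lab, hex=hexes, format=fmt)
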