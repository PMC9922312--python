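"""Pseudo-color codec for strain elastography overlays.

Strain elastography (EUS) renders tissue stiffness as a 256-level pseudo-color
ramp from blue (soft) to red (hard), alpha-blended additively on top of the
grayscale B-mode image (BUS).  This module provides the color bar, the
encode step (stiffness level -> RGB), the decode step (nearest color-bar
entry under Euclidean RGB distance), and the additive overlay / subtraction
pair that moves between BUS, pure-color and composite EUS images.

Decoding is exact by construction whenever the bar that produced the image is
supplied: each pixel of the pure-color image is compared against all 256 bar
entries and assigned the level whose entry minimises the squared RGB distance,
ties broken towards the smaller (softer) level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ColorBar",
    "default_color_bar",
    "extract_pure_color",
    "decode_pure_color",
    "encode_elasticity",
    "overlay",
]

N_LEVELS = 256


@dataclass(frozen=True)
class ColorBar:
    """Ordered lookup of 256 RGB triples; level 1 = softest (blue), 256 = hardest (red).

    Entries are stored as a (256, 3) uint8-valued integer array.  All entries
    must be pairwise distinct: injectivity is what makes decoding the exact
    inverse of encoding.
    """

    entries: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.entries, dtype=np.int64)
        if arr.shape != (N_LEVELS, 3):
            raise ValueError(f"color bar must have shape (256, 3), got {arr.shape}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("color bar entries must be 8-bit values in [0, 255]")
        if len({tuple(row) for row in arr.tolist()}) != N_LEVELS:
            raise ValueError("color bar entries must be pairwise distinct")
        object.__setattr__(self, "entries", arr)

    def scaled(self, weight: float) -> "ColorBar":
        """Bar with every channel multiplied by ``weight``.

        Used to decode images whose pure-color layer was blended at opacity
        ``weight`` < 1.  Requires the scaled values to be exact integers and
        still pairwise distinct, otherwise decoding could not be exact.
        """
        scaled = np.asarray(self.entries, dtype=np.float64) * weight
        rounded = np.rint(scaled)
        if not np.allclose(scaled, rounded, atol=1e-9):
            raise ValueError(
                f"bar entries times weight {weight} are not integers; "
                "exact decoding at this opacity is impossible"
            )
        return ColorBar(rounded.astype(np.int64))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"entries": self.entries.tolist()}))

    @classmethod
    def from_json(cls, path: str | Path) -> "ColorBar":
        data = json.loads(Path(path).read_text())
        return cls(np.asarray(data["entries"], dtype=np.int64))


def default_color_bar() -> ColorBar:
    """Deterministic blue-to-red bar with 256 distinct entries.

    The bar walks blue -> cyan -> green -> yellow -> red, changing exactly one
    channel by 4 between consecutive levels (a short initial blue ramp absorbs
    the 3 leftover transitions).  Every channel value is a multiple of 4, so
    the bar survives exact halving (`scaled(0.5)`), which the phantom's
    overlay relies on for lossless 8-bit round trips.
    """
    entries = []
    r, g, b = 0, 0, 240
    entries.append((r, g, b))

    def walk(n, dr, dg, db):
        nonlocal r, g, b
        for _ in range(n):
            r, g, b = r + dr, g + dg, b + db
            entries.append((r, g, b))

    walk(3, 0, 0, 4)      # deep blue ramp        -> (0, 0, 252)
    walk(63, 0, 4, 0)     # blue -> cyan          -> (0, 252, 252)
    walk(63, 0, 0, -4)    # cyan -> green         -> (0, 252, 0)
    walk(63, 4, 0, 0)     # green -> yellow       -> (252, 252, 0)
    walk(63, 0, -4, 0)    # yellow -> red         -> (252, 0, 0)
    return ColorBar(np.asarray(entries, dtype=np.int64))


def _as_gray(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    return arr


def _as_rgb(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {arr.shape}")
    return arr


def extract_pure_color(eus: np.ndarray, bus: np.ndarray) -> np.ndarray:
    """Subtract the B-mode image from the composite EUS, leaving the color layer.

    The BUS is replicated across the three channels and subtracted per pixel;
    negative differences are clamped to zero so the result stays in RGB space.
    """
    eus = _as_rgb(eus)
    bus = _as_gray(bus)
    if eus.shape[:2] != bus.shape:
        raise ValueError(
            f"dimension mismatch: eus {eus.shape[:2]} vs bus {bus.shape}"
        )
    diff = eus.astype(np.int64) - bus.astype(np.int64)[..., None]
    return np.clip(diff, 0, None)


def decode_pure_color(pure: np.ndarray, bar: ColorBar) -> np.ndarray:
    """Map each pure-color pixel to the nearest color-bar level (1..256).

    Nearest is Euclidean distance in RGB; the argmin is taken over squared
    distances in integer arithmetic, so there is no floating-point tie
    ambiguity, and exact ties go to the smaller level.
    """
    pure = _as_rgb(pure).astype(np.int64)
    h, w, _ = pure.shape
    flat = pure.reshape(-1, 3)
    bar_entries = bar.entries  # (256, 3) int64
    # (P, 256) squared distances; argmin returns the first (smallest) index on ties
    d2 = ((flat[:, None, :] - bar_entries[None, :, :]) ** 2).sum(axis=2)
    levels = d2.argmin(axis=1) + 1
    return levels.reshape(h, w)


def encode_elasticity(levels: np.ndarray, bar: ColorBar) -> np.ndarray:
    """Look up the bar entry for every level in a [1, 256] elasticity map."""
    levels = np.asarray(levels)
    bad = (levels < 1) | (levels > N_LEVELS)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"elasticity level {levels[idx]} at {idx} outside [1, 256]"
        )
    return bar.entries[levels.astype(np.int64) - 1]


def overlay(bus: np.ndarray, pure: np.ndarray, weight: float = 0.5) -> np.ndarray:
    """Blend a pure-color layer additively onto a grayscale B-mode image.

    The B-mode intensities are scaled into ``[0, (1-weight)*255]`` and the
    pure color into ``[0, weight*255]`` before addition (floor rounding), so
    the sum never clips and ``extract_pure_color`` recovers the scaled layer
    exactly.  ``bus`` is taken in [0, 255]; ``pure`` likewise.
    """
    bus = _as_gray(bus)
    pure = _as_rgb(pure)
    if pure.shape[:2] != bus.shape:
        raise ValueError(
            f"dimension mismatch: bus {bus.shape} vs pure {pure.shape[:2]}"
        )
    if not (0.0 < weight <= 1.0):
        raise ValueError(f"weight must be in (0, 1], got {weight}")
    bus_scaled = np.floor(bus.astype(np.float64) * (1.0 - weight)).astype(np.int64)
    pure_scaled = np.floor(pure.astype(np.float64) * weight).astype(np.int64)
    return (bus_scaled[..., None] + pure_scaled).astype(np.uint8)
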