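"""Strain-ratio and image-similarity quantification.

The strain ratio (SR) is the semi-quantitative stiffness score used to grade
breast lesions on strain elastography: the mean decoded elasticity level of
the tumor region divided by that of a 25x25-pixel normal-tissue reference
region placed at the same depth.  Stiffer tumors give larger SR, and larger
SR predicts malignancy.

Image agreement between a real elastogram and a synthesized one is measured
three ways:

* SSIM — structural similarity computed from global means, variances and the
  covariance of the two images (single window), averaged over RGB channels;
* MAPE — mean absolute percentage error between paired strain ratios;
* CHC — mean of the hue- and saturation-histogram correlations, where each
  correlation is ``1 - sqrt(1 - BC)`` with ``BC`` the Bhattacharyya
  coefficient of the two histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.color import rgb2hsv

__all__ = [
    "RoiBox",
    "StrainRatioResult",
    "SimilarityReport",
    "select_reference_region",
    "strain_ratio",
    "ssim",
    "mape",
    "chc",
    "similarity_report",
]


@dataclass(frozen=True)
class RoiBox:
    """0-based, half-open pixel box: rows [row, row+height), cols [col, col+width)."""

    row: int
    col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError(f"empty box: {self}")
        if self.row < 0 or self.col < 0:
            raise ValueError(f"negative origin: {self}")

    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.height),
                slice(self.col, self.col + self.width))

    def intersects(self, other: "RoiBox") -> bool:
        return not (self.row + self.height <= other.row or
                    other.row + other.height <= self.row or
                    self.col + self.width <= other.col or
                    other.col + other.width <= self.col)

    def check_within(self, shape: tuple[int, int]) -> None:
        if self.row + self.height > shape[0] or self.col + self.width > shape[1]:
            raise ValueError(f"box {self} exceeds image shape {shape}")


@dataclass(frozen=True)
class StrainRatioResult:
    sr: float
    tumor_mean_level: float
    reference_mean_level: float
    reference_box: RoiBox


@dataclass(frozen=True)
class SimilarityReport:
    ssim: float
    mape: float
    chc: float
    c1: float
    c2: float
    hue_bins: int
    sat_bins: int


def select_reference_region(levels: np.ndarray, roi: RoiBox, size: int = 25) -> RoiBox:
    """Place a ``size`` x ``size`` normal-tissue reference box at the tumor's depth.

    The box is centered (in rows) on the tumor ROI's row band and pushed
    laterally as far from the tumor as the image allows, i.e. flush to the
    image edge on the side with the wider lateral margin.  Deterministic.
    """
    levels = np.asarray(levels)
    H, W = levels.shape
    roi.check_within((H, W))
    center_row = roi.row + roi.height // 2
    top = int(np.clip(center_row - size // 2, 0, H - size))
    if H < size:
        raise ValueError(f"image height {H} cannot fit a {size}x{size} reference; "
                         "use a smaller size")
    left_margin = roi.col
    right_margin = W - (roi.col + roi.width)
    if max(left_margin, right_margin) < size:
        raise ValueError(
            f"no lateral margin fits a {size}x{size} reference box "
            f"(margins {left_margin}/{right_margin}); use a smaller size"
        )
    col = 0 if left_margin >= right_margin else W - size
    ref = RoiBox(top, col, size, size)
    return ref


def strain_ratio(levels: np.ndarray, roi: RoiBox, ref: RoiBox) -> StrainRatioResult:
    """Tumor mean elasticity level over reference mean elasticity level."""
    levels = np.asarray(levels, dtype=np.float64)
    roi.check_within(levels.shape)
    ref.check_within(levels.shape)
    if roi.intersects(ref):
        raise ValueError("tumor and reference boxes overlap")
    tumor_mean = float(levels[roi.slices()].mean())
    ref_mean = float(levels[ref.slices()].mean())
    return StrainRatioResult(
        sr=tumor_mean / ref_mean,
        tumor_mean_level=tumor_mean,
        reference_mean_level=ref_mean,
        reference_box=ref,
    )


def ssim(real: np.ndarray, virtual: np.ndarray, dynamic_range: float = 255.0,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Global (single-window) structural similarity between two images.

    Means, variances and the covariance are taken over the whole image, per
    channel, and the per-channel indices are averaged.  ``C1 = (k1*L)**2``
    and ``C2 = (k2*L)**2`` with ``L`` the declared dynamic range.
    """
    real = np.asarray(real, dtype=np.float64)
    virtual = np.asarray(virtual, dtype=np.float64)
    if real.shape != virtual.shape:
        raise ValueError(f"dimension mismatch: {real.shape} vs {virtual.shape}")
    if real.ndim == 2:
        real, virtual = real[..., None], virtual[..., None]
    c1 = (k1 * dynamic_range) ** 2
    c2 = (k2 * dynamic_range) ** 2
    vals = []
    for ch in range(real.shape[2]):
        x, y = real[..., ch].ravel(), virtual[..., ch].ravel()
        mx, my = x.mean(), y.mean()
        vx, vy = x.var(), y.var()
        cov = ((x - mx) * (y - my)).mean()
        vals.append(((2 * mx * my + c1) * (2 * cov + c2)) /
                    ((mx**2 + my**2 + c1) * (vx + vy + c2)))
    return float(np.mean(vals))


def mape(sr_real: Sequence[float], sr_virtual: Sequence[float]) -> float:
    """Mean absolute percentage error between paired strain ratios."""
    a = np.asarray(sr_real, dtype=np.float64)
    b = np.asarray(sr_virtual, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size == 0:
        raise ValueError("empty input")
    if (a <= 0).any():
        raise ValueError("all reference strain ratios must be strictly positive")
    return float(np.mean(np.abs(a - b) / a))


def _hc(cnt_a: np.ndarray, cnt_b: np.ndarray) -> float:
    # histogram correlation via the Bhattacharyya coefficient
    bc = np.sqrt(cnt_a * cnt_b).sum() / np.sqrt(cnt_a.sum() * cnt_b.sum())
    return float(1.0 - np.sqrt(max(0.0, 1.0 - bc)))


def chc(real: np.ndarray, virtual: np.ndarray,
        hue_bins: int = 50, sat_bins: int = 60) -> float:
    """Mean of hue- and saturation-histogram correlations of two RGB images."""
    real = np.asarray(real)
    virtual = np.asarray(virtual)
    if real.shape != virtual.shape:
        raise ValueError(f"dimension mismatch: {real.shape} vs {virtual.shape}")
    if real.ndim != 3 or real.shape[2] != 3:
        raise ValueError("chc expects (H, W, 3) RGB images")
    hsv_r = rgb2hsv(real)
    hsv_v = rgb2hsv(virtual)
    vals = []
    for ch, bins in ((0, hue_bins), (1, sat_bins)):
        cnt_r, _ = np.histogram(hsv_r[..., ch], bins=bins, range=(0.0, 1.0))
        cnt_v, _ = np.histogram(hsv_v[..., ch], bins=bins, range=(0.0, 1.0))
        vals.append(_hc(cnt_r.astype(np.float64), cnt_v.astype(np.float64)))
    return float(np.mean(vals))


def sr_from_images(eus: np.ndarray, bus: np.ndarray, bar, roi: RoiBox,
                   overlay_weight: float = 1.0,
                   ref_size: int = 25) -> StrainRatioResult:
    """Decode a composite elastogram and compute its strain ratio.

    ``bar`` is the color bar that produced the overlay; ``overlay_weight`` is
    the opacity the pure color was blended at (the bar is rescaled to match
    before nearest-color decoding).
    """
    from .codec import decode_pure_color, extract_pure_color

    scaled = bar.scaled(overlay_weight) if overlay_weight != 1.0 else bar
    levels = decode_pure_color(extract_pure_color(eus, bus), scaled)
    ref = select_reference_region(levels, roi, size=ref_size)
    return strain_ratio(levels, roi, ref)


def similarity_report(real: np.ndarray, virtual: np.ndarray,
                      sr_real: Sequence[float] | None = None,
                      sr_virtual: Sequence[float] | None = None,
                      dynamic_range: float = 255.0,
                      hue_bins: int = 50, sat_bins: int = 60) -> SimilarityReport:
    """Bundle SSIM, MAPE and CHC for one image pair (MAPE NaN when no SRs given)."""
    m = (mape(sr_real, sr_virtual)
         if sr_real is not None and sr_virtual is not None else float("nan"))
    return SimilarityReport(
        ssim=ssim(real, virtual, dynamic_range=dynamic_range),
        mape=m,
        chc=chc(real, virtual, hue_bins=hue_bins, sat_bins=sat_bins),
        c1=(0.01 * dynamic_range) ** 2,
        c2=(0.03 * dynamic_range) ** 2,
        hue_bins=hue_bins,
        sat_bins=sat_bins,
    )
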