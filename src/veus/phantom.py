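"""Synthetic paired B-mode / elastography phantom generator.

Clinical strain-elastography datasets of breast lesions are not publicly
distributable, so experiments here run on a seeded speckle phantom that
reproduces the statistical structure those experiments assume:

* a B-mode image (BUS) built as a smooth echogenicity background, multiplied
  by depth attenuation and a multiplicative Rayleigh speckle envelope, with a
  hypoechoic elliptical lesion whose echo intensity decreases monotonically
  with its stiffness (so the BUS genuinely carries elasticity cues for a
  translation model to learn);
* a co-registered ground-truth stiffness map on the 256-level scale, uniform
  background plus a label-dependent lesion level and smooth spatial noise
  (malignant lesions stiffer than benign ones);
* a composite EUS formed by additively overlaying the pseudo-color rendering
  of the stiffness map onto the BUS, with scaling chosen so the overlay is
  losslessly invertible in 8-bit arithmetic;
* optional attenuation artifacts for deep lesions: a vertical band of
  soft-end colors, uncorrelated with the true stiffness, replacing the
  pseudo-color below and inside the lesion (the ground truth is untouched —
  the artifact corrupts only the rendered EUS, as signal attenuation does).

All randomness flows through a single ``numpy.random.Generator`` per dataset,
so identical parameters and seed give byte-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .codec import ColorBar, default_color_bar, encode_elasticity, overlay

__all__ = [
    "PhantomParams",
    "CaseRecord",
    "generate_case",
    "generate_dataset",
    "inject_attenuation_artifact",
    "load_dataset",
]

BIRADS_SCALE = ("2", "3", "4a", "4b", "4c", "5")


@dataclass(frozen=True)
class PhantomParams:
    """Tunable description of the simulated acquisition.

    Depth is measured from the top image edge; rows deepen with depth.
    Stiffness is on the 256-level pseudo-color scale (1 = softest).
    """

    image_size: int = 256
    pixel_spacing: float = 0.15  # mm per pixel -> 38.4 mm field of view at 256
    lesion_axes_range: tuple[float, float] = (4.0, 12.0)  # semi-axes, mm
    lesion_depth_range: tuple[float, float] = (8.0, 32.0)  # center depth, mm
    stiffness_background: int = 64
    stiffness_benign_range: tuple[int, int] = (80, 140)
    stiffness_malignant_range: tuple[int, int] = (180, 245)
    speckle_scale: float = 0.35  # Rayleigh sigma of the multiplicative envelope
    attenuation_coeff: float = 0.02  # per-mm intensity decay
    artifact_prob_deep: float = 0.259
    artifact_depth_threshold: float = 20.0  # mm, lesion top edge
    overlay_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stiffness_malignant_range[0] <= self.stiffness_benign_range[1]:
            raise ValueError(
                "malignant stiffness interval must lie strictly above benign"
            )
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be >= 0")
        if not (0.0 < self.overlay_weight <= 1.0):
            raise ValueError("overlay_weight must be in (0, 1]")
        if not (0.0 <= self.artifact_prob_deep <= 1.0):
            raise ValueError("artifact_prob_deep must be a probability")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomParams":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown phantom parameters: {sorted(unknown)}")
        for key in ("lesion_axes_range", "lesion_depth_range",
                    "stiffness_benign_range", "stiffness_malignant_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class CaseRecord:
    """One registered BUS/EUS pair with ground truth (synthetic only)."""

    case_id: str
    bus: np.ndarray            # (H, W) uint8, rows deepen with depth
    eus: np.ndarray            # (H, W, 3) uint8
    stiffness_truth: np.ndarray  # (H, W) int levels in [1, 256]
    roi: tuple[int, int, int, int]  # row, col, height, width; 0-based half-open
    label: Literal["benign", "malignant"]
    tumor_depth_mm: float      # depth of the lesion's top edge
    birads: str
    artifact_flag: bool

    def __post_init__(self) -> None:
        if self.bus.shape != self.eus.shape[:2]:
            raise ValueError("bus and eus must share dimensions")
        r, c, h, w = self.roi
        H, W = self.bus.shape
        if not (0 <= r and 0 <= c and r + h <= H and c + w <= W and h > 0 and w > 0):
            raise ValueError(f"roi {self.roi} outside image bounds {(H, W)}")


def _smooth_field(rng: np.random.Generator, size: int, sigma: float,
                  lo: float, hi: float) -> np.ndarray:
    noise = rng.standard_normal((size, size))
    sm = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sm = (sm - sm.min()) / (np.ptp(sm) + 1e-12)
    return lo + (hi - lo) * sm


def _sample_lesion(params: PhantomParams, rng: np.random.Generator):
    """Sample ellipse geometry that fits inside the image; bounded retries."""
    n = params.image_size
    sp = params.pixel_spacing
    for _ in range(100):
        a_mm = rng.uniform(*params.lesion_axes_range)   # lateral semi-axis
        b_mm = rng.uniform(*params.lesion_axes_range)   # axial semi-axis
        depth_mm = rng.uniform(*params.lesion_depth_range)
        cr = depth_mm / sp
        cc = rng.uniform(0.25 * n, 0.75 * n)
        ar, ac = b_mm / sp, a_mm / sp
        if (cr - ar >= 1 and cr + ar <= n - 1 and
                cc - ac >= 1 and cc + ac <= n - 1):
            return cr, cc, ar, ac
    raise RuntimeError(
        "could not place a lesion inside the image after 100 retries; "
        "check lesion_depth_range / lesion_axes_range against image extent"
    )


def _sample_birads(label: str, rng: np.random.Generator) -> str:
    # Synthetic reader impression: benign lesions skew low, malignant high,
    # with overlap so BI-RADS alone is imperfect (as in practice).
    if label == "benign":
        cats, probs = ("2", "3", "4a", "4b"), (0.15, 0.50, 0.25, 0.10)
    else:
        cats, probs = ("4a", "4b", "4c", "5"), (0.15, 0.25, 0.35, 0.25)
    return str(rng.choice(cats, p=probs))


def generate_case(
    params: PhantomParams,
    label: Literal["benign", "malignant"],
    rng: np.random.Generator,
    case_id: str = "case",
    bar: ColorBar | None = None,
) -> CaseRecord:
    """Generate one paired case with known stiffness ground truth."""
    if label not in ("benign", "malignant"):
        raise ValueError(f"label must be 'benign' or 'malignant', got {label!r}")
    bar = bar or default_color_bar()
    n = params.image_size
    sp = params.pixel_spacing

    cr, cc, ar, ac = _sample_lesion(params, rng)
    rows, cols = np.mgrid[0:n, 0:n]
    inside = ((rows - cr) / ar) ** 2 + ((cols - cc) / ac) ** 2 <= 1.0

    # --- stiffness ground truth -------------------------------------------
    lo, hi = (params.stiffness_benign_range if label == "benign"
              else params.stiffness_malignant_range)
    lesion_level = rng.uniform(lo, hi)
    level_noise = _smooth_field(rng, n, sigma=6.0, lo=-6.0, hi=6.0)
    truth = np.full((n, n), float(params.stiffness_background))
    truth[inside] = lesion_level
    truth = np.clip(np.rint(truth + level_noise), 1, 256).astype(np.int64)

    # --- B-mode -------------------------------------------------------------
    background = _smooth_field(rng, n, sigma=12.0, lo=0.35, hi=0.75)
    # lesion echogenicity decreases monotonically with its stiffness level
    echo_factor = 0.85 - 0.65 * (lesion_level - 1.0) / 255.0
    bus = background.copy()
    bus[inside] *= echo_factor
    depth_mm = rows * sp
    bus *= np.exp(-params.attenuation_coeff * depth_mm)
    # multiplicative Rayleigh speckle envelope, normalised to unit mean
    envelope = rng.rayleigh(scale=params.speckle_scale, size=(n, n))
    envelope /= params.speckle_scale * np.sqrt(np.pi / 2.0)
    bus = np.clip(bus * envelope, 0.0, 1.0)
    bus_raw = np.floor(bus * 255.0).astype(np.uint8)

    # --- composite EUS (losslessly invertible overlay) ----------------------
    w = params.overlay_weight
    pure = encode_elasticity(truth, bar)
    eus = overlay(bus_raw, pure, weight=w)
    bus_stored = np.floor(bus_raw.astype(np.float64) * (1.0 - w)).astype(np.uint8)

    # ROI: bounding box of the ellipse
    r0, r1 = int(np.floor(cr - ar)), int(np.ceil(cr + ar)) + 1
    c0, c1 = int(np.floor(cc - ac)), int(np.ceil(cc + ac)) + 1
    r0, c0 = max(r0, 0), max(c0, 0)
    r1, c1 = min(r1, n), min(c1, n)
    roi = (r0, c0, r1 - r0, c1 - c0)

    case = CaseRecord(
        case_id=case_id,
        bus=bus_stored,
        eus=eus,
        stiffness_truth=truth,
        roi=roi,
        label=label,
        tumor_depth_mm=r0 * sp,
        birads=_sample_birads(label, rng),
        artifact_flag=False,
    )

    deep = case.tumor_depth_mm > params.artifact_depth_threshold
    if deep and rng.random() < params.artifact_prob_deep:
        case = inject_attenuation_artifact(case, rng, params=params, bar=bar)
    return case


def inject_attenuation_artifact(
    case: CaseRecord,
    rng: np.random.Generator,
    params: PhantomParams | None = None,
    bar: ColorBar | None = None,
) -> CaseRecord:
    """Corrupt the EUS of a deep lesion with an attenuation-style dropout band.

    A vertical band through the lesion's central columns, from the lesion's
    vertical midpoint down to the bottom edge of the image, is repainted with
    colors drawn from the soft (blue) end of the bar, uncorrelated with the
    true stiffness.  ``stiffness_truth`` is unchanged: attenuation corrupts
    the rendered elastogram, not the tissue.
    """
    params = params or PhantomParams()
    bar = bar or default_color_bar()
    if case.tumor_depth_mm <= params.artifact_depth_threshold:
        import warnings

        warnings.warn(
            "lesion shallower than the artifact depth threshold; no-op",
            stacklevel=2,
        )
        return case

    r, c, h, wdt = case.roi
    n_rows = case.bus.shape[0]
    # the shadow spans the lesion laterally and everything beneath it, as
    # attenuation kills the strain signal in and below the deep lesion
    band_half = max(1, int(rng.uniform(0.5, 0.65) * wdt))
    c_mid = c + wdt // 2
    c0, c1 = max(0, c_mid - band_half), min(case.bus.shape[1], c_mid + band_half)
    r0 = max(0, r + int(rng.uniform(0.0, 0.2) * h))

    # soft-end levels, independent of the truth map
    soft_levels = rng.integers(1, 33, size=(n_rows - r0, c1 - c0)) + \
        rng.integers(0, 2, size=(n_rows - r0, c1 - c0))
    soft_pure = encode_elasticity(soft_levels, bar)
    w = params.overlay_weight
    soft_scaled = np.floor(soft_pure.astype(np.float64) * w).astype(np.int64)

    eus = case.eus.astype(np.int64).copy()
    eus[r0:, c0:c1] = case.bus.astype(np.int64)[r0:, c0:c1, None] + soft_scaled
    return dataclasses.replace(case, eus=eus.astype(np.uint8), artifact_flag=True)


def generate_dataset(
    params: PhantomParams,
    n_cases: int,
    malignant_fraction: float = 0.5,
    seed: int | None = None,
    out_dir: str | Path | None = None,
    bar: ColorBar | None = None,
) -> list[CaseRecord]:
    """Generate a dataset of cases; optionally write PNGs + manifest to disk.

    The benign/malignant split is allocated deterministically (``round(n *
    fraction)`` malignant cases, interleaved), not sampled, so the composition
    is exact.  With ``out_dir`` set, writes per-case ``<id>_bus.png``,
    ``<id>_eus.png``, ``<id>_truth.png`` (level - 1 as 8-bit), a
    ``manifest.csv`` and the parameters as ``params.yaml``.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not (0.0 <= malignant_fraction <= 1.0):
        raise ValueError("malignant_fraction must be in [0, 1]")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    bar = bar or default_color_bar()

    n_mal = int(round(n_cases * malignant_fraction))
    labels = np.full(n_cases, "benign", dtype=object)
    if n_mal:
        labels[np.linspace(0, n_cases - 1, n_mal).astype(int)] = "malignant"

    cases = [
        generate_case(params, lab, rng, case_id=f"case{i:05d}", bar=bar)
        for i, lab in enumerate(labels)
    ]

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for case in cases:
            iio.imwrite(out / f"{case.case_id}_bus.png", case.bus)
            iio.imwrite(out / f"{case.case_id}_eus.png", case.eus)
            iio.imwrite(out / f"{case.case_id}_truth.png",
                        (case.stiffness_truth - 1).astype(np.uint8))
            rows.append({
                "case_id": case.case_id,
                "label": case.label,
                "roi_row": case.roi[0], "roi_col": case.roi[1],
                "roi_height": case.roi[2], "roi_width": case.roi[3],
                "tumor_depth_mm": case.tumor_depth_mm,
                "birads": case.birads,
                "artifact_flag": case.artifact_flag,
            })
        pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
        params.to_yaml(out / "params.yaml")
        bar.to_json(out / "colorbar.json")
    return cases


def load_dataset(out_dir: str | Path) -> list[CaseRecord]:
    """Reload a dataset written by :func:`generate_dataset`."""
    out = Path(out_dir)
    manifest = pd.read_csv(out / "manifest.csv", dtype={"birads": str})
    cases = []
    for row in manifest.itertuples(index=False):
        truth = iio.imread(out / f"{row.case_id}_truth.png").astype(np.int64) + 1
        cases.append(CaseRecord(
            case_id=row.case_id,
            bus=iio.imread(out / f"{row.case_id}_bus.png"),
            eus=iio.imread(out / f"{row.case_id}_eus.png"),
            stiffness_truth=truth,
            roi=(int(row.roi_row), int(row.roi_col),
                 int(row.roi_height), int(row.roi_width)),
            label=row.label,
            tumor_depth_mm=float(row.tumor_depth_mm),
            birads=str(row.birads),
            artifact_flag=bool(row.artifact_flag),
        ))
    return cases
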