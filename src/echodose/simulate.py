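"""Synthetic B-mode data for dose-response experiments.

Percutaneous electrolysis delivers galvanic current through a needle; on
B-mode ultrasound the electrochemical reaction shows up as hyperechoic foci
(hydrogen gas microbubbles) whose number and extent grow with the applied
current and saturate at high intensities, with posterior acoustic shadowing
under strong gas pockets.  No public image set exists for this protocol, so
this module provides:

* the experimental dose schedule (29 intensities, 0.00-10.00 mA);
* a speckle + planted-lesion image generator with exact ground truth, for
  testing the segmentation and texture stages;
* a tabular feature/dose generator with known linear-model parameters, for
  statistical parameter-recovery experiments.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DoseSchedule",
    "SpeckleParams",
    "LesionModel",
    "GroundTruth",
    "FeatureGenModel",
    "UltrasoundFrame",
    "make_dose_schedule",
    "simulate_speckle_background",
    "plant_lesions",
    "generate_image_dataset",
    "generate_feature_table",
]

# Composite dose-index coefficients used as generator truth (mA per unit):
# intercept, area (cm^2), count, perimeter (cm).
DEFAULT_INTERCEPT = 0.542
DEFAULT_COEF_AREA = -316.88
DEFAULT_COEF_NUMBER = -2.678
DEFAULT_COEF_PERIMETER = 20.284


@dataclass(frozen=True)
class UltrasoundFrame:
    """8-bit grayscale B-mode raster with physical pixel spacing and dose label."""

    pixels: np.ndarray  # uint8, (rows, cols)
    pixel_spacing: float  # cm per pixel (isotropic)
    dose: float = 0.0  # mA

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class DoseSchedule:
    """Ordered list of applied current intensities in mA."""

    doses: tuple[float, ...]

    def __post_init__(self) -> None:
        d = np.asarray(self.doses)
        if d.size == 0 or np.any(np.diff(d) <= 0) or d[0] < 0:
            raise ValueError("doses must be strictly increasing and non-negative")

    def __len__(self) -> int:
        return len(self.doses)

    def __iter__(self):
        return iter(self.doses)


@dataclass(frozen=True)
class SpeckleParams:
    """Fully-developed-speckle background parameters.

    The envelope is modeled as Rayleigh-distributed; ``speckle_scale`` blends
    between a flat field (0) and fully developed speckle (1) around
    ``background_mean``.
    """

    image_height: int = 256
    image_width: int = 256
    pixel_spacing: float = 0.01  # cm/pixel
    background_mean: float = 60.0  # gray level
    speckle_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        if not 0 <= self.background_mean <= 255:
            raise ValueError("background mean must lie in [0, 255]")


def _default_foci_rate(d: float) -> float:
    """Saturating mean focus count: minimal below 1 mA, growth 1-4 mA, plateau above."""
    return 8.0 * d * d / (d * d + 9.0)


def _default_focus_radius(d: float) -> float:
    """Mean focus radius in cm, growing mildly with dose."""
    return 0.03 + 0.025 * d / (d + 3.0)


def _default_irregularity(d: float) -> float:
    """Relative boundary-perturbation amplitude, growing with dose.

    Emulates the progressive loss of geometric regularity of the affected
    areas at higher currents: foci are near-circular at low dose and develop
    lobulated boundaries as the dose rises.
    """
    return 0.45 * d / (d + 3.0)


@dataclass(frozen=True)
class LesionModel:
    """Dose-dependent hyperechoic-focus model.

    foci_rate
        mean number of foci as a function of dose (monotone, 0 at dose 0).
    focus_radius
        mean focus radius in cm as a function of dose.
    irregularity
        relative amplitude of low-order harmonic boundary perturbation as a
        function of dose (0 gives perfect discs).
    intensity_boost
        gray-level increment of a focus over the local background.
    shadow_threshold
        dose (mA) above which posterior acoustic shadowing is applied.
    shadow_attenuation
        multiplicative factor (<1) applied to pixels below each focus.
    min_separation
        if set, minimum center distance (cm) enforced between foci
        (rejection sampling); useful for segmentation ground-truth tests.
    """

    foci_rate: Callable[[float], float] = _default_foci_rate
    focus_radius: Callable[[float], float] = _default_focus_radius
    irregularity: Callable[[float], float] = _default_irregularity
    intensity_boost: float = 90.0
    shadow_threshold: float = 4.0
    shadow_attenuation: float = 0.6
    min_separation: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.shadow_attenuation < 1:
            raise ValueError("shadow attenuation must lie in (0, 1)")


@dataclass(frozen=True)
class GroundTruth:
    """Planted-lesion ground truth for one frame."""

    centers: tuple[tuple[float, float], ...]  # (row, col) pixels
    radii: tuple[float, ...]  # pixels
    mask: np.ndarray  # bool, union of planted discs
    dose: float

    @property
    def count(self) -> int:
        return len(self.centers)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dose_mA": self.dose,
            "centers_px": [list(c) for c in self.centers],
            "radii_px": list(self.radii),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def make_dose_schedule() -> DoseSchedule:
    """The experiment's 29-intensity schedule.

    0.10 mA increments from 0.00 to 1.00 mA, then 0.50 mA increments up to
    the 10.00 mA maximum.
    """
    fine = [round(0.1 * i, 2) for i in range(11)]  # 0.00 .. 1.00
    coarse = [round(1.0 + 0.5 * i, 2) for i in range(1, 19)]  # 1.50 .. 10.00
    return DoseSchedule(doses=tuple(fine + coarse))


def simulate_speckle_background(params: SpeckleParams) -> UltrasoundFrame:
    """Rayleigh-envelope speckle field quantized to 8 bits.

    Pixel = background_mean * (1 + s*(R - 1)) with R Rayleigh-distributed with
    unit mean, so the field has mean ``background_mean`` for any blend s and
    degenerates to a constant at s = 0.
    """
    rng = np.random.default_rng(params.seed)
    # Rayleigh with unit mean: scale = sqrt(2/pi)
    r = rng.rayleigh(scale=np.sqrt(2.0 / np.pi),
                     size=(params.image_height, params.image_width))
    field = params.background_mean * (1.0 + params.speckle_scale * (r - 1.0))
    pixels = np.clip(np.rint(field), 0, 255).astype(np.uint8)
    return UltrasoundFrame(pixels=pixels, pixel_spacing=params.pixel_spacing, dose=0.0)


def plant_lesions(
    frame: UltrasoundFrame,
    dose: float,
    model: LesionModel | None = None,
    seed: int = 0,
) -> tuple[UltrasoundFrame, GroundTruth]:
    """Plant dose-dependent hyperechoic foci into a background frame.

    The focus count is Poisson with mean ``model.foci_rate(dose)``; each focus
    is a disc brightened by ``intensity_boost``.  Above ``shadow_threshold``
    the column strip below each focus is multiplicatively attenuated,
    emulating posterior acoustic shadowing from accumulated gas.
    """
    if dose < 0:
        raise ValueError("dose must be non-negative")
    model = model or LesionModel()
    rng = np.random.default_rng(seed)
    rows, cols = frame.shape
    out = frame.pixels.astype(np.float64)
    mask = np.zeros((rows, cols), dtype=bool)

    n = int(rng.poisson(model.foci_rate(dose)))
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    mean_r_px = model.focus_radius(dose) / frame.pixel_spacing
    margin = max(4.0, 2.0 * mean_r_px)
    yy, xx = np.mgrid[0:rows, 0:cols]

    for _ in range(n):
        for _attempt in range(200):
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            if model.min_separation is None:
                break
            sep_px = model.min_separation / frame.pixel_spacing
            if all(np.hypot(cr - r0, cc - c0) >= sep_px for r0, c0 in centers):
                break
        else:
            continue  # could not place under the separation constraint
        radius = max(1.5, rng.normal(mean_r_px, 0.15 * mean_r_px))
        amp = model.irregularity(dose)
        if amp > 0:
            # star-shaped blob: radius modulated by 2nd-4th angular harmonics
            coeffs = rng.normal(0.0, 1.0, size=(3, 2)) / np.sqrt(3.0)
            theta = np.arctan2(yy - cr, xx - cc)
            mod = np.zeros_like(theta)
            for k, (a, b) in zip((2, 3, 4), coeffs):
                mod += a * np.cos(k * theta) + b * np.sin(k * theta)
            local_r = np.maximum(radius * (1.0 + amp * mod), 1.0)
        else:
            local_r = radius
        disc = (yy - cr) ** 2 + (xx - cc) ** 2 <= local_r**2
        out[disc] += model.intensity_boost
        mask |= disc
        centers.append((cr, cc))
        radii.append(radius)

    if dose > model.shadow_threshold:
        for (cr, cc), radius in zip(centers, radii):
            c0 = max(0, int(np.floor(cc - radius)))
            c1 = min(cols, int(np.ceil(cc + radius)) + 1)
            r0 = min(rows, int(np.ceil(cr + radius)) + 1)
            out[r0:, c0:c1] *= model.shadow_attenuation

    pixels = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    gt = GroundTruth(centers=tuple(centers), radii=tuple(radii), mask=mask, dose=dose)
    return (
        UltrasoundFrame(pixels=pixels, pixel_spacing=frame.pixel_spacing, dose=dose),
        gt,
    )


def generate_image_dataset(
    schedule: DoseSchedule | None = None,
    params: SpeckleParams | None = None,
    model: LesionModel | None = None,
    seed: int = 0,
) -> list[tuple[UltrasoundFrame, GroundTruth]]:
    """One speckle + lesion frame per schedule entry.

    Per-frame seeds are ``seed + index`` so individual frames can be
    regenerated without rebuilding the whole set.
    """
    schedule = schedule or make_dose_schedule()
    params = params or SpeckleParams()
    model = model or LesionModel()
    dataset = []
    for i, dose in enumerate(schedule):
        p = SpeckleParams(
            image_height=params.image_height,
            image_width=params.image_width,
            pixel_spacing=params.pixel_spacing,
            background_mean=params.background_mean,
            speckle_scale=params.speckle_scale,
            seed=seed + i,
        )
        bg = simulate_speckle_background(p)
        # offset the lesion stream so it is independent of the speckle stream
        frame, gt = plant_lesions(bg, dose, model, seed=seed + i + 10_000)
        dataset.append((frame, gt))
    return dataset


@dataclass(frozen=True)
class FeatureGenModel:
    """Latent-factor generator for (A_Area, A_Number, A_Perimeter, dose) tables.

    Features are linear in three shared standard-normal factors, which makes
    their covariance available in closed form; dose is the composite linear
    model applied to the features plus Gaussian residual noise.  Loadings are
    chosen so that the marginal feature scales match a cm-unit ultrasound
    pipeline (areas of a few hundredths of cm^2, perimeters under a cm).
    """

    mean_area: float = 0.030  # cm^2
    mean_number: float = 2.0
    mean_perimeter: float = 0.80  # cm
    # loadings on z1, z2, z3
    load_number: tuple[float, float, float] = (0.8, 0.0, 0.0)
    load_area: tuple[float, float, float] = (0.006, 0.008, 0.0)
    load_perimeter: tuple[float, float, float] = (0.125, 0.075, 0.20)
    intercept: float = DEFAULT_INTERCEPT
    coef_area: float = DEFAULT_COEF_AREA
    coef_number: float = DEFAULT_COEF_NUMBER
    coef_perimeter: float = DEFAULT_COEF_PERIMETER
    sigma: float = 0.3  # residual SD, mA

    def covariance(self) -> np.ndarray:
        """Closed-form covariance of (A_Area, A_Number, A_Perimeter)."""
        loads = np.array([self.load_area, self.load_number, self.load_perimeter])
        return loads @ loads.T


def generate_feature_table(
    n: int,
    model: FeatureGenModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw n (A_Area, A_Number, A_Perimeter, dose_mA) rows from the generator.

    Features are unclipped Gaussians (negative draws are rare at the default
    means and clipping would bias coefficient recovery); dose is the linear
    composite model plus N(0, sigma^2) noise.
    """
    if n < 4:
        raise ValueError("need at least 4 rows for a 3-predictor regression")
    model = model or FeatureGenModel()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 3))
    area = model.mean_area + z @ np.asarray(model.load_area)
    number = model.mean_number + z @ np.asarray(model.load_number)
    perimeter = model.mean_perimeter + z @ np.asarray(model.load_perimeter)
    dose = (
        model.intercept
        + model.coef_area * area
        + model.coef_number * number
        + model.coef_perimeter * perimeter
        + model.sigma * rng.standard_normal(n)
    )
    return pd.DataFrame(
        {"A_Area": area, "A_Number": number, "A_Perimeter": perimeter, "dose_mA": dose}
    )
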