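"""End-to-end orchestration: simulate -> extract -> analyze -> report.

A single YAML-configurable pipeline reproduces the whole experiment from one
master seed: synthetic B-mode frames for the 29-intensity dose schedule,
per-frame feature extraction into a CSV, and the dose-response statistical
report.  Every run writes a manifest (seed, configuration, package versions)
sufficient to reproduce its outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .lesions import SegmentationConfig, extract_A_features
from .simulate import (
    LesionModel,
    SpeckleParams,
    UltrasoundFrame,
    generate_image_dataset,
    make_dose_schedule,
)
from .stats import StatReport, run_full_analysis
from .texture import TextureConfig, extract_B_features

logger = logging.getLogger("echodose")

__all__ = [
    "PipelineConfig",
    "validate_config",
    "run_pipeline",
    "simulate_stage",
    "extract_stage",
    "analyze_stage",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "dose_mA",
    "A_Number", "A_Area", "A_Perimeter", "A_Convexity",
    "A_Homogeneity", "A_Contrast", "A_ASM",
    "B_GLCM_Contrast", "B_GLCM_SumAverage", "B_GLCM_SoSVariance",
    "B_GLCM_DVariance", "B_GLCM_Correlation", "B_GLCM_IDMoment",
    "B_GLDS_Homogeneity", "B_GLDS_Contrast", "B_GLDS_ASM",
    "B_GLDS_Entropy", "B_GLDS_Mean", "B_haar_mean", "B_haar_variance",
)


@dataclass(frozen=True)
class SpeckleSettings:
    image_height: int = 256
    image_width: int = 256
    pixel_spacing: float = 0.01
    background_mean: float = 60.0
    speckle_scale: float = 0.5


@dataclass(frozen=True)
class LesionSettings:
    """Parametric form of the dose-dependent lesion model.

    Mean focus count is rate_max * d^2 / (d^2 + rate_half_dose^2); mean focus
    radius is radius_base_cm + radius_gain_cm * d / (d + rate_half_dose).
    """

    rate_max: float = 8.0
    rate_half_dose: float = 3.0
    radius_base_cm: float = 0.03
    radius_gain_cm: float = 0.025
    intensity_boost: float = 90.0
    shadow_threshold: float = 4.0
    shadow_attenuation: float = 0.6


@dataclass(frozen=True)
class SegmentationSettings:
    k: float = 3.0
    min_size: int = 20
    connectivity: int = 8


@dataclass(frozen=True)
class TextureSettings:
    levels: int = 32
    displacement: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class StatsSettings:
    boundaries: tuple[float, float] = (1.0, 4.0)
    p_remove: float = 0.10


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    speckle: SpeckleSettings = field(default_factory=SpeckleSettings)
    lesion: LesionSettings = field(default_factory=LesionSettings)
    segmentation: SegmentationSettings = field(default_factory=SegmentationSettings)
    texture: TextureSettings = field(default_factory=TextureSettings)
    stats: StatsSettings = field(default_factory=StatsSettings)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    # -- derived library objects ------------------------------------------
    def speckle_params(self, seed: int | None = None) -> SpeckleParams:
        s = self.speckle
        return SpeckleParams(
            image_height=s.image_height, image_width=s.image_width,
            pixel_spacing=s.pixel_spacing, background_mean=s.background_mean,
            speckle_scale=s.speckle_scale, seed=self.seed if seed is None else seed,
        )

    def lesion_model(self) -> LesionModel:
        l = self.lesion
        return LesionModel(
            foci_rate=lambda d: l.rate_max * d * d / (d * d + l.rate_half_dose**2),
            focus_radius=lambda d: l.radius_base_cm
            + l.radius_gain_cm * d / (d + l.rate_half_dose),
            intensity_boost=l.intensity_boost,
            shadow_threshold=l.shadow_threshold,
            shadow_attenuation=l.shadow_attenuation,
        )

    def segmentation_config(self) -> SegmentationConfig:
        s = self.segmentation
        return SegmentationConfig(
            k=s.k, min_size=s.min_size, connectivity=s.connectivity,
            pixel_spacing=self.speckle.pixel_spacing,
        )

    def texture_config(self) -> TextureConfig:
        t = self.texture
        return TextureConfig(levels=t.levels, displacement=tuple(t.displacement))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str, errors: list[str]):
    """Recursively construct a settings dataclass, collecting key/type errors."""
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            errors.append(f"unknown key: {path}{key}")
            continue
        f = known[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "speckle", "lesion", "segmentation", "texture", "stats"
        ):
            sub_cls = {
                "speckle": SpeckleSettings, "lesion": LesionSettings,
                "segmentation": SegmentationSettings, "texture": TextureSettings,
                "stats": StatsSettings,
            }[f.name]
            if not isinstance(value, dict):
                errors.append(f"{path}{key}: expected a mapping")
                continue
            kwargs[key] = _build(sub_cls, value, f"{path}{key}.", errors)
        else:
            if isinstance(value, list):
                value = tuple(value)
            if isinstance(value, bool) or not isinstance(value, (int, float, tuple)):
                errors.append(f"{path}{key}: expected a number, got {value!r}")
                continue
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{path.rstrip('.') or 'config'}: {exc}")
        return None


def validate_config(file: str | Path | None = None) -> PipelineConfig:
    """Load and type-check a YAML pipeline configuration.

    An empty or absent file yields the full-default configuration; unknown
    keys and type mismatches are reported together with their key paths.
    """
    data: dict = {}
    if file is not None:
        text = Path(file).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError("config root must be a mapping")
            data = loaded
    errors: list[str] = []
    cfg = _build(PipelineConfig, data, "", errors)
    if errors or cfg is None:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# stages


def simulate_stage(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Generate the dose-schedule image set; write PNG frames + sidecars."""
    out = Path(out_dir)
    images = out / "images"
    images.mkdir(parents=True, exist_ok=True)
    schedule = make_dose_schedule()
    dataset = generate_image_dataset(
        schedule, config.speckle_params(), config.lesion_model(), seed=config.seed
    )
    rows = []
    for i, (frame, gt) in enumerate(dataset):
        name = f"frame_{i:03d}"
        iio.imwrite(images / f"{name}.png", frame.pixels)
        gt.to_json(images / f"{name}.json")
        rows.append({"frame": f"{name}.png", "dose_mA": frame.dose})
    pd.DataFrame(rows).to_csv(out / "doses.csv", index=False)
    logger.info("simulate: wrote %d frames to %s", len(rows), images)
    return out / "doses.csv"


def extract_stage(
    config: PipelineConfig, images_dir: str | Path, doses_csv: str | Path,
    out_csv: str | Path,
) -> pd.DataFrame:
    """Extract the 20-component feature vector for every listed frame."""
    images_dir = Path(images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"image directory not found: {images_dir}")
    doses = pd.read_csv(doses_csv)
    seg = config.segmentation_config()
    tex = config.texture_config()
    rows = []
    for _, rec in doses.iterrows():
        path = images_dir / rec["frame"]
        pixels = np.asarray(iio.imread(path))
        frame = UltrasoundFrame(
            pixels=pixels, pixel_spacing=config.speckle.pixel_spacing,
            dose=float(rec["dose_mA"]),
        )
        a = extract_A_features(frame, seg, tex)
        b = extract_B_features(frame, config=tex)
        rows.append({"dose_mA": frame.dose, **a.as_dict(), **b.as_dict()})
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))
    table.to_csv(out_csv, index=False)
    logger.info("extract: wrote %d feature rows to %s", len(table), out_csv)
    return table


def analyze_stage(
    config: PipelineConfig, features: pd.DataFrame, out_dir: str | Path
) -> StatReport:
    """Run the statistical phase and write its tables + JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = run_full_analysis(
        features, boundaries=config.stats.boundaries, p_remove=config.stats.p_remove
    )
    report.correlations.to_csv(out / "correlations.csv")
    report.simple_ols.to_csv(out / "simple_ols.csv")
    report.group_comparison.to_csv(out / "group_comparison.csv")
    features.assign(UZ_eDosis=report.composite.to_numpy()).to_csv(
        out / "features_with_composite.csv", index=False
    )
    bw = report.backward
    summary = {
        "backward_elimination": {
            "predictors": list(bw.predictors),
            "eliminated": list(bw.eliminated),
            "coefficients": {k: float(v) for k, v in bw.params.items()},
            "p_values": {k: float(v) for k, v in bw.pvalues.items()},
            "R": bw.r, "R2": bw.r2, "R2_adjusted": bw.r2_adj,
            "F": bw.f, "F_p": bw.f_p,
        },
        "n_samples": int(len(features)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    logger.info("analyze: report written to %s", out)
    return report


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> StatReport:
    """Execute simulate -> extract -> analyze and write a run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doses_csv = simulate_stage(config, out)
    features = extract_stage(config, out / "images", doses_csv, out / "features.csv")
    report = analyze_stage(config, features, out / "report")
    manifest = {
        "echodose_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return report
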