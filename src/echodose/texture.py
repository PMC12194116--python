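"""Whole-ROI echotexture descriptors: GLCM (Haralick), GLDS and Haar statistics.

B-mode speckle carries diagnostic information in its second-order gray-level
statistics.  This module implements the three descriptor families used for
whole-window texture characterization of ultrasound frames:

* gray-level co-occurrence matrix (GLCM) features after Haralick — contrast,
  sum average, sum-of-squares variance, difference variance, correlation and
  inverse difference moment;
* gray-level difference statistics (GLDS) — mean, contrast, angular second
  moment, entropy and homogeneity of the absolute-difference histogram;
* first-level 2-D Haar wavelet detail statistics.

All features operate on a uniformly quantized raster (default 32 levels) so
that the co-occurrence tables stay small and comparable across frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from skimage.feature import graycomatrix

__all__ = [
    "GLCMatrix",
    "GLDSHistogram",
    "BFeatures",
    "TextureConfig",
    "quantize",
    "glcm",
    "glcm_features",
    "glds",
    "glds_features",
    "haar_features",
    "extract_B_features",
]

#: unit-distance offsets (row, col) at 0, 45, 90 and 135 degrees
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class GLCMatrix:
    """Normalized symmetric co-occurrence table pooled over an offset set."""

    p: np.ndarray  # (L, L), sums to 1
    levels: int
    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.p.shape != (self.levels, self.levels):
            raise ValueError("co-occurrence table shape must be (levels, levels)")


@dataclass(frozen=True)
class GLDSHistogram:
    """Distribution g(k) of absolute gray-level differences at one displacement."""

    g: np.ndarray  # (L,), sums to 1
    displacement: tuple[int, int]


@dataclass(frozen=True)
class TextureConfig:
    """Quantization and geometry settings for the texture operators.

    levels
        number of uniform gray-level bins (applied to the 0..255 range).
    offsets
        GLCM pixel offsets pooled into a single symmetric matrix.
    displacement
        GLDS displacement vector (row, col).
    """

    levels: int = 32
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS
    displacement: tuple[int, int] = (0, 1)


@dataclass(frozen=True)
class BFeatures:
    """Per-frame whole-window texture feature vector."""

    B_GLCM_Contrast: float
    B_GLCM_SumAverage: float
    B_GLCM_SoSVariance: float
    B_GLCM_DVariance: float
    B_GLCM_Correlation: float
    B_GLCM_IDMoment: float
    B_GLDS_Homogeneity: float
    B_GLDS_Contrast: float
    B_GLDS_ASM: float
    B_GLDS_Entropy: float
    B_GLDS_Mean: float
    B_haar_mean: float
    B_haar_variance: float

    def as_dict(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.__dict__.items()}


def quantize(frame: np.ndarray, levels: int = 32) -> np.ndarray:
    """Uniformly bin an 8-bit raster into ``levels`` gray levels 0..levels-1.

    The binning is monotone and surjective for full-range input: level
    ``floor(v * levels / 256)``.
    """
    if levels < 2:
        raise ValueError("quantization needs at least 2 levels")
    arr = np.asarray(frame)
    q = (arr.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1).astype(np.uint8)


def glcm(
    quantized: np.ndarray,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    levels: int | None = None,
    symmetric: bool = True,
) -> GLCMatrix:
    """Pooled, symmetrized, normalized co-occurrence matrix.

    Pair counts for every offset are accumulated into one table; offsets that
    do not fit inside the raster contribute nothing.  Raises if no offset
    yields any pair.
    """
    arr = np.asarray(quantized)
    if arr.size == 0:
        raise ValueError("empty raster")
    if levels is None:
        levels = int(arr.max()) + 1

    # graycomatrix takes (distance, angle); map each integer offset onto it.
    # angle convention: offset (dr, dc) = (-d*sin(theta), d*cos(theta)).
    total = np.zeros((levels, levels), dtype=np.float64)
    rows, cols = arr.shape
    for dr, dc in offsets:
        if abs(dr) >= rows or abs(dc) >= cols:
            continue
        d = float(np.hypot(dr, dc))
        theta = np.arctan2(-dr, dc)
        m = graycomatrix(
            arr, distances=[d], angles=[theta], levels=levels,
            symmetric=symmetric, normed=False,
        )
        total += m[:, :, 0, 0].astype(np.float64)
    s = total.sum()
    if s == 0:
        raise ValueError("no valid pixel pairs for the given offsets")
    return GLCMatrix(p=total / s, levels=levels, offsets=tuple(offsets))


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """Six Haralick descriptors of a normalized symmetric co-occurrence table.

    Correlation is defined as 0 when either marginal is degenerate (constant
    window), so the feature stays finite on flat tissue.
    """
    p = m.p
    L = m.levels
    i = np.arange(L, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)
    mu_x = float(np.dot(i, px))
    py = p.sum(axis=0)
    mu_y = float(np.dot(i, py))
    var_x = float(np.dot((i - mu_x) ** 2, px))
    var_y = float(np.dot((i - mu_y) ** 2, py))

    contrast = float(np.sum((ii - jj) ** 2 * p))
    idmoment = float(np.sum(p / (1.0 + (ii - jj) ** 2)))

    # p_{x+y}(k), k = 0..2L-2
    ksum = (ii + jj).astype(np.int64)
    p_sum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * L - 1)
    sum_average = float(np.dot(np.arange(2 * L - 1), p_sum))

    sos_variance = float(np.sum((ii - mu_x) ** 2 * p))

    # p_{x-y}(k) over the signed difference k = i-j
    kdiff = (ii - jj).astype(np.int64) + (L - 1)
    p_diff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=2 * L - 1)
    kd = np.arange(2 * L - 1, dtype=np.float64) - (L - 1)
    mu_d = float(np.dot(kd, p_diff))
    d_variance = float(np.dot((kd - mu_d) ** 2, p_diff))

    denom = np.sqrt(var_x * var_y)
    if denom <= 0:
        correlation = 0.0
    else:
        correlation = float((np.sum(ii * jj * p) - mu_x * mu_y) / denom)

    return {
        "B_GLCM_Contrast": contrast,
        "B_GLCM_SumAverage": sum_average,
        "B_GLCM_SoSVariance": sos_variance,
        "B_GLCM_DVariance": d_variance,
        "B_GLCM_Correlation": correlation,
        "B_GLCM_IDMoment": idmoment,
    }


def glds(
    quantized: np.ndarray,
    displacement: tuple[int, int] = (0, 1),
    levels: int | None = None,
) -> GLDSHistogram:
    """Normalized histogram of |I(x) - I(x + delta)| over all valid pixels."""
    dr, dc = displacement
    if (dr, dc) == (0, 0):
        raise ValueError("GLDS displacement must be nonzero")
    arr = np.asarray(quantized).astype(np.int64)
    rows, cols = arr.shape
    if abs(dr) >= rows or abs(dc) >= cols:
        raise ValueError("displacement larger than raster")
    if levels is None:
        levels = int(arr.max()) + 1

    r0, r1 = max(0, -dr), min(rows, rows - dr)
    c0, c1 = max(0, -dc), min(cols, cols - dc)
    a = arr[r0:r1, c0:c1]
    b = arr[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    diffs = np.abs(a - b)
    g = np.bincount(diffs.ravel(), minlength=levels).astype(np.float64)
    return GLDSHistogram(g=g / g.sum(), displacement=(dr, dc))


def glds_features(h: GLDSHistogram) -> dict[str, float]:
    """Five summary statistics of a gray-level difference histogram."""
    g = h.g
    k = np.arange(g.size, dtype=np.float64)
    nz = g > 0
    entropy = float(-np.sum(g[nz] * np.log(g[nz])))
    return {
        "B_GLDS_Homogeneity": float(np.sum(g / (1.0 + k))),
        "B_GLDS_Contrast": float(np.dot(k**2, g)),
        "B_GLDS_ASM": float(np.dot(g, g)),
        "B_GLDS_Entropy": entropy,
        "B_GLDS_Mean": float(np.dot(k, g)),
    }


def haar_features(frame: np.ndarray) -> tuple[float, float]:
    """Mean and variance of pooled |detail| coefficients of a one-level Haar DWT.

    Odd trailing rows/columns are cropped so the transform is boundary-free.
    The detail bands (LH, HL, HH) annihilate constants, so both statistics are
    invariant to adding a constant gray level.
    """
    arr = np.asarray(frame, dtype=np.float64)
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("frame must be at least 2x2")
    arr = arr[: arr.shape[0] - arr.shape[0] % 2, : arr.shape[1] - arr.shape[1] % 2]
    _, (lh, hl, hh) = pywt.dwt2(arr, "haar")
    detail = np.abs(np.concatenate([lh.ravel(), hl.ravel(), hh.ravel()]))
    return float(detail.mean()), float(detail.var())


def extract_B_features(
    frame: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    config: TextureConfig | None = None,
) -> BFeatures:
    """Compute the full 13-component B feature vector on one frame.

    Parameters
    ----------
    frame
        8-bit grayscale raster (or an object exposing ``.pixels``).
    roi
        (row0, col0, row1, col1) half-open window; whole frame if omitted.
    config
        quantization levels, GLCM offsets and GLDS displacement.
    """
    cfg = config or TextureConfig()
    pixels = np.asarray(getattr(frame, "pixels", frame))
    if roi is not None:
        r0, c0, r1, c1 = roi
        pixels = pixels[r0:r1, c0:c1]
    if pixels.size == 0:
        raise ValueError("empty ROI")

    q = quantize(pixels, cfg.levels)
    gm = glcm(q, offsets=cfg.offsets, levels=cfg.levels)
    vals: dict[str, float] = glcm_features(gm)
    vals.update(glds_features(glds(q, cfg.displacement, levels=cfg.levels)))
    hm, hv = haar_features(pixels)
    vals["B_haar_mean"] = hm
    vals["B_haar_variance"] = hv
    return BFeatures(**vals)
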