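"""The 56-feature battery computed per image tile.

For each of the four grayscale conversions the battery computes four feature
families:

* histogram moments — Mean, SD, Skewness, Kurtosis of pixel intensities;
* GLCM texture — ASM, Contrast, Correlation, IDM, Entropy of the gray-level
  co-occurrence matrix (distance 1, four directions averaged, symmetric);
* local orientation — SD, Skewness, Kurtosis of the per-pixel structure
  orientation (the mean is deliberately excluded: it only reflects how the
  section happened to lie on the slide);
* binary measures — TC-ratio (foreground fraction after Triangle
  thresholding) and box-counting fractal dimension of the binary mask.

4 strategies x (4 + 5 + 3 + 2) = 56 named features per tile.

Conventions for degenerate inputs (constant images, empty masks) are chosen
so every feature is always finite; they are documented on each function.
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage.feature import graycomatrix

from . import convert as _convert
from .types import STRATEGIES, GrayImage, RGBTile

__all__ = [
    "GLCMatrix",
    "OrientationMap",
    "BinaryImage",
    "FeatureConfig",
    "FEATURE_NAMES",
    "FAMILY_FEATURE_NAMES",
    "histogram_features",
    "build_glcm",
    "glcm_features",
    "orientation_map",
    "orientation_features",
    "triangle_threshold",
    "triangle_threshold_from_histogram",
    "binarize",
    "tc_ratio",
    "fractal_dimension",
    "extract_feature_vector",
    "extract_table",
]

#: Per-strategy feature names, in stable column order.
FAMILY_FEATURE_NAMES = (
    "histogram.Mean",
    "histogram.SD",
    "histogram.Skewness",
    "histogram.Kurtosis",
    "glcm.ASM",
    "glcm.Contrast",
    "glcm.Correlation",
    "glcm.IDM",
    "glcm.Entropy",
    "helmholtz.SD",
    "helmholtz.Skewness",
    "helmholtz.Kurtosis",
    "binary.TCratio",
    "binary.FD",
)

#: The full 56-name feature vector layout: "{strategy}.{family}.{name}".
FEATURE_NAMES = tuple(
    f"{s}.{name}" for s in STRATEGIES for name in FAMILY_FEATURE_NAMES
)


# ---------------------------------------------------------------------------
# histogram moments


def _moment_stats(values: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sample SD, skewness, excess kurtosis) of a 1-D sample.

    SD uses the n-1 denominator; skewness and kurtosis use population central
    moments m3/m2^1.5 and m4/m2^2 - 3 (the conventions of ImageJ "Measure").
    A constant sample yields (value, 0, 0, 0).
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("cannot compute moments of an empty sample")
    n = v.size
    mean = v.mean()
    d = v - mean
    d2 = d * d
    m2 = d2.mean()
    if m2 <= 0:
        return float(mean), 0.0, 0.0, 0.0
    sd = math.sqrt(d2.sum() / (n - 1)) if n > 1 else 0.0
    m3 = (d2 * d).mean()
    m4 = (d2 * d2).mean()
    return float(mean), sd, float(m3 / m2**1.5), float(m4 / m2**2 - 3.0)


def _moment_stats_from_counts(
    counts: np.ndarray,
) -> tuple[float, float, float, float]:
    """Same conventions as :func:`_moment_stats`, from a value histogram."""
    counts = np.asarray(counts, dtype=float)
    values = np.arange(counts.size, dtype=float)
    n = counts.sum()
    mean = (values * counts).sum() / n
    d = values - mean
    d2 = d * d
    m2 = (d2 * counts).sum() / n
    if m2 <= 0:
        return float(mean), 0.0, 0.0, 0.0
    sd = math.sqrt((d2 * counts).sum() / (n - 1)) if n > 1 else 0.0
    m3 = (d2 * d * counts).sum() / n
    m4 = (d2 * d2 * counts).sum() / n
    return float(mean), sd, float(m3 / m2**1.5), float(m4 / m2**2 - 3.0)


def histogram_features(img: GrayImage | np.ndarray) -> tuple[float, float, float, float]:
    """Mean, SD, Skewness and excess Kurtosis of the intensity histogram."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if pixels.size == 0:
        raise ValueError("empty image")
    if pixels.dtype == np.uint8:
        # moments from the 256-bin histogram: exact and O(1) in image size
        return _moment_stats_from_counts(np.bincount(pixels.ravel(), minlength=256))
    return _moment_stats(pixels)


# ---------------------------------------------------------------------------
# GLCM texture


@dataclass(eq=False)
class GLCMatrix:
    """A normalized gray-level co-occurrence matrix (directions averaged)."""

    probabilities: np.ndarray
    levels: int
    distance: int = 1
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    symmetric: bool = True

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("GLCM must be square")
        self.probabilities = p


def build_glcm(
    img: GrayImage | np.ndarray,
    distance: int = 1,
    angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0),
    symmetric: bool = True,
    levels: int = 256,
) -> GLCMatrix:
    """Count co-occurring pixel pairs at the given offset(s), normalized.

    With 256 levels the 8-bit image is used as-is (no requantization).  Each
    direction's matrix is normalized to probabilities first and the
    normalized matrices are then averaged, so directions with different pair
    counts contribute equally.
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    if distance < 1:
        raise ValueError("offset distance must be >= 1")
    if distance >= min(pixels.shape):
        raise ValueError("offset distance must be smaller than the image")
    if not 8 <= levels <= 256:
        raise ValueError("levels must be in [8, 256]")
    if levels < 256:
        pixels = (pixels.astype(np.uint16) * levels // 256).astype(np.uint8)
    glcm = graycomatrix(
        pixels,
        distances=[distance],
        angles=list(np.deg2rad(angles_deg)),
        levels=levels,
        symmetric=symmetric,
        normed=True,
    )
    p = glcm[:, :, 0, :].mean(axis=2)
    return GLCMatrix(p, levels, distance, tuple(angles_deg), symmetric)


def glcm_features(M: GLCMatrix | np.ndarray) -> tuple[float, float, float, float, float]:
    """ASM, Contrast, Correlation, IDM and Entropy of a normalized GLCM.

    Entropy uses the natural logarithm with 0 ln 0 := 0.  Correlation is 0
    by convention when either marginal standard deviation vanishes (e.g. a
    constant image).
    """
    p = M.probabilities if isinstance(M, GLCMatrix) else np.asarray(M, dtype=float)
    total = p.sum()
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ValueError("GLCM is not normalized to probabilities")
    g = p.shape[0]
    i = np.arange(g, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    asm = float((p * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    nz = p[p > 0]
    entropy = float(-(nz * np.log(nz)).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    var_x = float(((i - mu_x) ** 2) @ px)
    var_y = float(((i - mu_y) ** 2) @ py)
    denom = math.sqrt(var_x * var_y)
    if denom <= 0:
        correlation = 0.0
    else:
        correlation = float(((ii - mu_x) * (jj - mu_y) * p).sum() / denom)
    return asm, contrast, correlation, idm, entropy


# ---------------------------------------------------------------------------
# local orientation ("Helmholtz" analysis)


@dataclass(eq=False)
class OrientationMap:
    """Per-pixel structure orientation in degrees, range (-90, 90].

    ``valid`` is False where the local gradient energy is below tolerance
    (no oriented structure to measure).
    """

    angles_deg: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if self.angles_deg.shape != self.valid.shape:
            raise ValueError("angle and validity maps must share a shape")


def orientation_map(
    img: GrayImage | np.ndarray,
    window_sigma: float = 2.0,
    energy_rtol: float = 1e-6,
) -> OrientationMap:
    """Local structure orientation from the 2x2 structure tensor.

    The tensor J is the Gaussian-windowed outer product of the image
    gradient; the structure (not gradient) orientation is
    ``1/2 * atan2(2 J_rc, J_rr - J_cc)`` with (r, c) the row/column axes,
    mapped to (-90, 90] degrees where 0 means horizontal structures.
    Pixels whose tensor energy (trace) falls below ``energy_rtol`` times the
    maximum energy are flagged invalid.
    """
    if window_sigma <= 0:
        raise ValueError("window_sigma must be positive")
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    # float32 + a 3-sigma kernel cutoff keep the Gaussian windows cheap;
    # angle precision stays far below the degree scale of the statistics
    g = pixels.astype(np.float32)
    d_r, d_c = np.gradient(g)
    smooth = functools.partial(
        ndi.gaussian_filter, sigma=window_sigma, mode="nearest", truncate=3.0
    )
    a_rr = smooth(d_r * d_r)
    a_rc = smooth(d_r * d_c)
    a_cc = smooth(d_c * d_c)
    angle = 0.5 * np.degrees(np.arctan2(2.0 * a_rc, a_rr - a_cc))
    # atan2 yields (-180, 180]/2 = (-90, 90]; pin -90 (if produced by
    # floating point) onto +90 to keep the half-open range.
    angle = np.where(angle <= -90.0, angle + 180.0, angle)
    energy = a_rr + a_cc
    valid = energy > energy_rtol * float(energy.max(initial=0.0))
    return OrientationMap(angle, valid)


def orientation_features(omap: OrientationMap) -> tuple[float, float, float]:
    """SD, Skewness and excess Kurtosis of the valid orientation angles.

    Plain (non-circular) moments on the angle values.  Fewer than two valid
    pixels yields (0, 0, 0).
    """
    angles = omap.angles_deg[omap.valid]
    if angles.size < 2:
        return 0.0, 0.0, 0.0
    _, sd, skew, kurt = _moment_stats(angles)
    return sd, skew, kurt


# ---------------------------------------------------------------------------
# Triangle thresholding and binary measures


def triangle_threshold_from_histogram(hist: np.ndarray) -> int:
    """Zack Triangle threshold on a 256-bin histogram.

    Geometric construction: draw the line from the histogram peak to the
    farthest non-empty tail bin (the longer tail; ties take the bright
    side), then pick the bin between them that maximizes the perpendicular
    distance to that line.  Ties on the distance take the bin closest to the
    peak.  A single-bin histogram returns that bin.
    """
    h = np.asarray(hist, dtype=float)
    if h.ndim != 1 or h.size < 1 or (h < 0).any():
        raise ValueError("histogram must be 1-D with non-negative counts")
    nonzero = np.flatnonzero(h)
    if nonzero.size == 0:
        raise ValueError("histogram is empty")
    peak = int(h.argmax())
    lo, hi = int(nonzero[0]), int(nonzero[-1])
    if lo == hi:
        return lo
    tail = lo if (peak - lo) > (hi - peak) else hi
    if tail == peak:  # peak sits on the only non-empty extreme
        tail = lo if tail == hi else hi
    a, b = (peak, tail) if peak < tail else (tail, peak)
    idx = np.arange(a, b + 1, dtype=float)
    # |cross product| distance from (i, h_i) to the peak-tail line
    dx, dy = float(tail - peak), h[tail] - h[peak]
    dist = np.abs(dx * (h[a : b + 1] - h[peak]) - dy * (idx - peak))
    best = np.flatnonzero(dist == dist.max()) + a
    return int(best[np.abs(best - peak).argmin()])


def triangle_threshold(img: GrayImage | np.ndarray) -> int:
    """Triangle threshold of an 8-bit image (constant image -> its value)."""
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    hist = np.bincount(pixels.ravel().astype(np.uint8), minlength=256)
    return triangle_threshold_from_histogram(hist)


@dataclass(eq=False)
class BinaryImage:
    """A thresholded image: True marks foreground (stained structures)."""

    mask: np.ndarray
    threshold_value: int
    method: str = "triangle"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)


def binarize(img: GrayImage | np.ndarray, invert: bool = False) -> BinaryImage:
    """Binarize with the Triangle threshold.

    Foreground is the set of pixels *below* the threshold: stained
    structures are darker than background in bright-field images.  With
    ``invert=True`` the polarity flips (foreground = at/above threshold).
    """
    pixels = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    t = triangle_threshold(pixels)
    mask = pixels >= t if invert else pixels < t
    return BinaryImage(mask, t)


def tc_ratio(b: BinaryImage | np.ndarray) -> float:
    """Foreground fraction of a binary mask (in [0, 1])."""
    mask = b.mask if isinstance(b, BinaryImage) else np.asarray(b, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(mask.mean())


def _box_counts(mask: np.ndarray, s: int) -> int:
    """Number of s x s grid boxes (anchored at (0, 0)) touching foreground."""
    h, w = mask.shape
    ph, pw = (-h) % s, (-w) % s
    if ph or pw:
        mask = np.pad(mask, ((0, ph), (0, pw)))
    hh, ww = mask.shape
    blocks = mask.reshape(hh // s, s, ww // s, s).any(axis=(1, 3))
    return int(blocks.sum())


def fractal_dimension(b: BinaryImage | np.ndarray) -> float:
    """Box-counting fractal dimension of the foreground mask.

    Boxes of side 2, 4, 8, ... up to min(H, W)/4 on a grid anchored at the
    origin; FD is the least-squares slope of log N(s) against log(1/s) over
    sizes with N(s) > 0.  An empty mask returns 0 by convention.
    """
    mask = b.mask if isinstance(b, BinaryImage) else np.asarray(b, dtype=bool)
    if not mask.any():
        return 0.0
    max_size = min(mask.shape) // 4
    sizes = []
    s = 2
    while s <= max_size:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError("mask too small for box counting (need min side >= 16)")
    counts = np.array([_box_counts(mask, s) for s in sizes], dtype=float)
    keep = counts > 0
    slope, _ = np.polyfit(np.log(1.0 / np.array(sizes, float)[keep]), np.log(counts[keep]), 1)
    return float(slope)


# ---------------------------------------------------------------------------
# the assembled 56-feature vector


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the feature battery."""

    stain_vectors: _convert.StainVectors = field(
        default_factory=_convert.default_stain_vectors
    )
    weights_8bw: tuple[float, float, float] = _convert.DEFAULT_8BW_WEIGHTS
    glcm_distance: int = 1
    glcm_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    glcm_symmetric: bool = True
    glcm_levels: int = 256
    orientation_sigma: float = 2.0


def _family_features(gray: GrayImage, cfg: FeatureConfig) -> dict[str, float]:
    mean, sd, skew, kurt = histogram_features(gray)
    glcm = build_glcm(
        gray,
        distance=cfg.glcm_distance,
        angles_deg=cfg.glcm_angles_deg,
        symmetric=cfg.glcm_symmetric,
        levels=cfg.glcm_levels,
    )
    asm, contrast, correlation, idm, entropy = glcm_features(glcm)
    osd, oskew, okurt = orientation_features(
        orientation_map(gray, cfg.orientation_sigma)
    )
    binary = binarize(gray)
    return {
        "histogram.Mean": mean,
        "histogram.SD": sd,
        "histogram.Skewness": skew,
        "histogram.Kurtosis": kurt,
        "glcm.ASM": asm,
        "glcm.Contrast": contrast,
        "glcm.Correlation": correlation,
        "glcm.IDM": idm,
        "glcm.Entropy": entropy,
        "helmholtz.SD": osd,
        "helmholtz.Skewness": oskew,
        "helmholtz.Kurtosis": okurt,
        "binary.TCratio": tc_ratio(binary),
        "binary.FD": fractal_dimension(binary),
    }


def extract_feature_vector(
    tile: RGBTile, config: FeatureConfig | None = None
) -> dict[str, float]:
    """The full 56-feature descriptor of one tile (stable key order)."""
    cfg = config or FeatureConfig()
    out: dict[str, float] = {}
    for strategy in STRATEGIES:
        gray = _convert.convert(
            tile, strategy, vectors=cfg.stain_vectors, weights=cfg.weights_8bw
        )
        for name, value in _family_features(gray, cfg).items():
            out[f"{strategy}.{name}"] = value
    if len(out) != len(FEATURE_NAMES):
        raise RuntimeError("feature battery produced an unexpected key set")
    bad = [k for k, v in out.items() if not math.isfinite(v)]
    if bad:
        warnings.warn(f"non-finite features replaced by 0: {bad}")
        for k in bad:
            out[k] = 0.0
    return out


def extract_table(
    tiles, config: FeatureConfig | None = None
) -> pd.DataFrame:
    """Stack per-tile feature vectors into a table.

    Columns: tile_id, label, patient_id, size, then the 56 features in
    :data:`FEATURE_NAMES` order.
    """
    rows = []
    for tile in tiles:
        row = {
            "tile_id": tile.tile_id,
            "label": tile.label,
            "patient_id": tile.patient_id,
            "size": tile.size,
        }
        row.update(extract_feature_vector(tile, config))
        rows.append(row)
    columns = ["tile_id", "label", "patient_id", "size", *FEATURE_NAMES]
    return pd.DataFrame(rows, columns=columns)
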