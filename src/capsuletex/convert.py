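"""RGB -> 8-bit conversion strategies for H&E bright-field tiles.

Four strategies produce the grayscale images that feed the feature battery:

``8b``
    unweighted channel mean, round((R + G + B) / 3);
``8bw``
    perceptual weighting 0.299 R + 0.587 G + 0.114 B;
``RED``
    the red channel alone (eosin stains collagen in reds and pinks, so the
    red channel carries most of the capsule signal);
``EOSIN``
    the eosin channel recovered by color deconvolution, rendered back to a
    bright-field-like transmittance image (255 = no eosin).

Color deconvolution follows the Beer-Lambert model: per channel the optical
density is OD_c = -log10(I_c / I_0), and the OD vector of a pixel is a
non-negative mixture of unit stain OD vectors.  Inverting the stain matrix
unmixes the pixel into per-stain concentrations.  The same forward model is
exposed as :func:`synthesize_rgb` so that synthetic tiles round-trip through
the deconvolution exactly (up to 8-bit quantization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GrayImage, RGBTile, _as_uint8

__all__ = [
    "StainVectors",
    "convert",
    "convert_8b",
    "convert_8bw",
    "convert_red",
    "convert_eosin",
    "deconvolve_he",
    "synthesize_rgb",
]

#: Standard published H&E optical-density vectors (R, G, B), pre-normalization.
HEMATOXYLIN_OD = (0.650, 0.704, 0.286)
EOSIN_OD = (0.072, 0.990, 0.105)

DEFAULT_8BW_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class StainVectors:
    """An invertible basis of three unit optical-density vectors.

    Rows of ``matrix`` are the hematoxylin, eosin and residual OD vectors in
    (R, G, B) order.  The residual completes the basis (cross product of the
    two stains) and should be empty when the stain vectors match the image.
    """

    matrix: np.ndarray
    background: int = 255

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("stain matrix must be 3 x 3")
        norms = np.linalg.norm(m, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("stain vectors must have unit Euclidean norm")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("stain matrix is singular")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_stains(
        cls,
        hematoxylin: tuple[float, float, float] = HEMATOXYLIN_OD,
        eosin: tuple[float, float, float] = EOSIN_OD,
        background: int = 255,
    ) -> "StainVectors":
        """Build a basis from two stain vectors; residual by cross product."""
        h = np.asarray(hematoxylin, dtype=float)
        e = np.asarray(eosin, dtype=float)
        h = h / np.linalg.norm(h)
        e = e / np.linalg.norm(e)
        r = np.cross(h, e)
        nr = np.linalg.norm(r)
        if nr < 1e-12:
            raise ValueError("hematoxylin and eosin vectors are collinear")
        return cls(np.stack([h, e, r / nr]), background=background)

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)


def default_stain_vectors() -> StainVectors:
    return StainVectors.from_stains()


def _pixels(tile: RGBTile | np.ndarray) -> np.ndarray:
    if isinstance(tile, RGBTile):
        return tile.pixels
    return np.asarray(tile)


def _tile_id(tile: RGBTile | np.ndarray) -> str:
    return tile.tile_id if isinstance(tile, RGBTile) else ""


def convert_8b(tile: RGBTile | np.ndarray) -> GrayImage:
    """Unweighted RGB mean, rounded half away from zero."""
    rgb = _pixels(tile).astype(float)
    return GrayImage(_as_uint8(rgb.mean(axis=2)), "8b", _tile_id(tile))


def convert_8bw(
    tile: RGBTile | np.ndarray,
    weights: tuple[float, float, float] = DEFAULT_8BW_WEIGHTS,
) -> GrayImage:
    """Weighted RGB -> 8-bit conversion (default: perceptual weights)."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (3,) or (w < 0).any():
        raise ValueError("weights must be three non-negative reals")
    rgb = _pixels(tile).astype(float)
    return GrayImage(_as_uint8(rgb @ w), "8bw", _tile_id(tile))


def convert_red(tile: RGBTile | np.ndarray) -> GrayImage:
    """The red channel, untouched."""
    return GrayImage(_pixels(tile)[..., 0].copy(), "RED", _tile_id(tile))


def deconvolve_he(
    tile: RGBTile | np.ndarray, vectors: StainVectors | None = None
) -> np.ndarray:
    """Unmix a bright-field RGB tile into per-stain concentration maps.

    Returns an (H, W, 3) float array of optical-density concentrations in
    (hematoxylin, eosin, residual) order.  Intensities are clamped to >= 1
    before the log so the OD stays bounded; negative concentrations (stain
    vectors not exactly matching the pixel) are clamped to zero.
    """
    vectors = vectors or default_stain_vectors()
    rgb = _pixels(tile).astype(float)
    od = -np.log10(np.clip(rgb, 1.0, None) / vectors.background)
    conc = od @ vectors.inverse
    return np.clip(conc, 0.0, None)


def synthesize_rgb(
    concentrations: np.ndarray, vectors: StainVectors | None = None
) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations -> 8-bit RGB transmittance.

    ``concentrations`` is (H, W, 3) in (hematoxylin, eosin, residual) order;
    the result is the uint8 image ``I_0 * 10**(-(C @ M))`` that
    :func:`deconvolve_he` inverts.
    """
    vectors = vectors or default_stain_vectors()
    conc = np.asarray(concentrations, dtype=float)
    od = conc @ vectors.matrix
    return _as_uint8(vectors.background * 10.0 ** (-od))


def convert_eosin(
    tile: RGBTile | np.ndarray, vectors: StainVectors | None = None
) -> GrayImage:
    """Eosin channel as a bright-field-like image (255 = no eosin).

    The eosin concentration map is mapped back through the transmittance law
    ``round(I_0 * 10**(-c_eosin))`` so that brighter means less stain,
    matching the semantics of the other three strategies.
    """
    vectors = vectors or default_stain_vectors()
    c_eosin = deconvolve_he(tile, vectors)[..., 1]
    out = _as_uint8(vectors.background * 10.0 ** (-c_eosin))
    return GrayImage(out, "EOSIN", _tile_id(tile))


def convert(
    tile: RGBTile | np.ndarray,
    strategy: str,
    vectors: StainVectors | None = None,
    weights: tuple[float, float, float] = DEFAULT_8BW_WEIGHTS,
) -> GrayImage:
    """Dispatch to one of the four conversion strategies by name."""
    strategy_norm = strategy.upper() if strategy.lower() != "8bw" else "8bw"
    if strategy in ("8b", "8B"):
        return convert_8b(tile)
    if strategy_norm == "8bw":
        return convert_8bw(tile, weights)
    if strategy_norm == "RED":
        return convert_red(tile)
    if strategy_norm == "EOSIN":
        return convert_eosin(tile, vectors)
    raise ValueError(f"unknown conversion strategy: {strategy!r}")
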