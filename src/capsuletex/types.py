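"""Shared domain containers for capsule-texture analysis.

The pipeline moves 8-bit RGB tiles (one per region of interest on a nodule
capsule) through grayscale conversion, feature extraction and classification.
The two containers here are deliberately thin wrappers around numpy arrays:
they carry the provenance metadata (class label, patient, conversion
strategy) that the patient-level splitting downstream depends on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The three diagnostic classes: follicular adenoma, papillary thyroid
#: carcinoma, and PTC arising within a follicular adenoma.
CLASSES = ("FA", "PTC", "PTCFA")

#: The four RGB -> 8-bit conversion strategies.
STRATEGIES = ("8b", "8bw", "RED", "EOSIN")


def round_half_away(x: np.ndarray | float) -> np.ndarray:
    """Round halves away from zero (numpy's default rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _as_uint8(x: np.ndarray) -> np.ndarray:
    return np.clip(round_half_away(x), 0, 255).astype(np.uint8)


@dataclass(eq=False)
class RGBTile:
    """A square 8-bit RGB image tile with its diagnostic label and patient.

    Parameters
    ----------
    pixels : (size, size, 3) uint8 array
    label : class label, one of :data:`CLASSES` for cohort tiles
    patient_id : identifier of the patient the tile was cropped from
    tile_id : unique identifier of the tile
    fiber_mask : optional (size, size) bool array of the planted fiber
        foreground; attached by the synthetic generator, ignored elsewhere.
    """

    pixels: np.ndarray
    label: str
    patient_id: str
    tile_id: str
    fiber_mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("tile pixels must be an H x W x 3 array")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("tiles are square: H must equal W")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if not self.label:
            raise ValueError("label must be non-empty")
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(eq=False)
class GrayImage:
    """An 8-bit single-channel image tagged with its conversion strategy."""

    pixels: np.ndarray
    strategy: str
    source_tile_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("gray image must be 2-D")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("intensities must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
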