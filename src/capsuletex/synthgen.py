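"""Synthetic labeled cohorts of H&E-like fiber-texture tiles.

Whole-slide images of nodule capsules are not publicly available, so the
pipeline is exercised on rendered stand-ins: bands of sinusoidally wavy,
partially aligned fibers colored through the same Beer-Lambert H&E forward
model that the conversion module inverts.  Each generative knob excites one
feature family:

* total stain optical density        -> histogram Mean (brightness);
* OD modulation depth                -> histogram SD, GLCM Contrast;
* fiber wavelength / waviness / the
  number of superposed wave systems  -> GLCM texture, fractal dimension;
* orientation spread                 -> orientation statistics;
* eosin vs hematoxylin split         -> RED and EOSIN channel content.

Tiles are organized into patients; a per-patient random brightness offset
makes patient-level splitting genuinely different from tile-level splitting.
Everything is reproducible bit-for-bit from the cohort seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import convert as _convert
from .types import CLASSES, RGBTile, _as_uint8

__all__ = [
    "FiberParams",
    "CohortSpec",
    "DEFAULT_CLASS_EFFECTS",
    "make_fiber_tile",
    "make_cohort",
    "crop_nested",
    "write_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class FiberParams:
    """Generative parameters of one tile class.

    Optical densities are in Beer-Lambert OD units (1.0 transmits 10% of
    light); lengths are in pixels; angles in degrees.
    """

    hematoxylin_od: float = 0.25
    eosin_od: float = 0.55
    od_contrast: float = 0.45  # modulation depth of the OD field over fibers
    wavelength: float = 28.0  # fiber spacing
    fiber_width: float = 0.12  # Gaussian fiber half-width, fraction of spacing
    waviness: float = 6.0  # displacement amplitude of the fiber warp
    warp_wavelength: float = 96.0  # wavelength of the low-frequency warp
    orientation_deg: float = 0.0  # dominant fiber direction
    orientation_jitter_deg: float = 12.0  # spread of per-wave orientations
    n_waves: int = 4  # superposed fiber systems
    noise_sd: float = 2.0  # additive intensity noise, 8-bit units

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.hematoxylin_od < 0 or self.eosin_od < 0:
            raise ValueError("stain optical densities must be non-negative")
        if self.wavelength <= 0 or self.warp_wavelength <= 0:
            raise ValueError("wavelengths must be positive")
        if self.n_waves < 1:
            raise ValueError("need at least one wave system")
        if self.waviness < 0 or self.od_contrast < 0:
            raise ValueError("waviness and od_contrast must be non-negative")
        if not 0 < self.fiber_width < 0.5:
            raise ValueError("fiber_width is a fraction of the spacing in (0, 0.5)")


#: Class-specific generative parameters.  The planted contrasts mirror the
#: qualitative orderings reported for capsule tiles: PTC capsules image
#: brightest (loosest collagen, least total stain), FA darkest but
#: eosin-heavy (so FA stays brighter than PTCFA in the red channel), FA most
#: complex/wavy (highest fractal dimension) and PTCFA most compact.
DEFAULT_CLASS_EFFECTS: dict[str, FiberParams] = {
    "FA": FiberParams(
        hematoxylin_od=0.28,
        eosin_od=0.85,
        od_contrast=0.55,
        wavelength=24.0,
        waviness=10.0,
        orientation_jitter_deg=18.0,
        n_waves=5,
    ),
    "PTC": FiberParams(
        hematoxylin_od=0.18,
        eosin_od=0.55,
        od_contrast=0.40,
        wavelength=32.0,
        waviness=6.0,
        orientation_jitter_deg=12.0,
        n_waves=4,
    ),
    "PTCFA": FiberParams(
        hematoxylin_od=0.52,
        eosin_od=0.58,
        od_contrast=0.30,
        wavelength=28.0,
        waviness=3.0,
        orientation_jitter_deg=8.0,
        n_waves=3,
    ),
}


def _fiber_field(size: int, p: FiberParams, rng: np.random.Generator) -> np.ndarray:
    """Fiber density field in [0, 1]: Gaussian-profile ridges on background.

    Each of the ``n_waves`` fiber systems lays down parallel ridges (spacing
    ``wavelength``, Gaussian cross-profile of width ``fiber_width`` times the
    spacing) at a jittered orientation, displaced sinusoidally along the
    fiber direction ("waviness").  Systems combine by maximum, so ridges
    stay crisp where they cross — yielding the bimodal intensity histogram
    of stained fiber bands on a brighter background.
    """
    rows, cols = np.mgrid[0:size, 0:size].astype(float)
    total = np.zeros((size, size))
    for _ in range(p.n_waves):
        theta = np.deg2rad(
            p.orientation_deg + rng.uniform(-p.orientation_jitter_deg, p.orientation_jitter_deg)
        )
        # u: coordinate across the fibers; v: along them.  A fiber running
        # at angle theta from the column axis is constant along v.
        u = rows * np.cos(theta) + cols * np.sin(theta)
        v = -rows * np.sin(theta) + cols * np.cos(theta)
        warp = p.waviness * np.sin(
            2 * np.pi * v / p.warp_wavelength + rng.uniform(0, 2 * np.pi)
        )
        pos = (u + warp) / p.wavelength + rng.uniform(0, 1)
        dist = np.abs(pos - np.round(pos))  # distance to nearest ridge crest
        np.maximum(total, np.exp(-0.5 * (dist / p.fiber_width) ** 2), out=total)
    return total


def make_fiber_tile(
    size: int,
    params: FiberParams | None = None,
    seed: int = 0,
    *,
    label: str = "FA",
    patient_id: str = "P00",
    tile_id: str | None = None,
    stain_vectors: _convert.StainVectors | None = None,
) -> RGBTile:
    """Render one synthetic fiber tile.

    The fiber field f in [0, 1] modulates the stain-density field
    ``g = 0.5 + od_contrast * f`` (a stained background plus denser
    fibers) which scales both stain concentrations; the RGB pixel is the
    Beer-Lambert transmittance of that mixture plus additive Gaussian
    noise, clamped to [0, 255].  The planted fiber foreground (field above
    its profile half-maximum) is attached as ``fiber_mask``.
    """
    if size < 64:
        raise ValueError("tile size must be >= 64")
    p = params or FiberParams()
    vectors = stain_vectors or _convert.default_stain_vectors()
    rng = np.random.default_rng(seed)
    f = _fiber_field(size, p, rng)
    g = 0.5 + p.od_contrast * f
    conc = np.zeros((size, size, 3))
    conc[..., 0] = p.hematoxylin_od * g
    conc[..., 1] = p.eosin_od * g
    rgb = _convert.synthesize_rgb(conc, vectors).astype(float)
    if p.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, p.noise_sd, rgb.shape)
    return RGBTile(
        _as_uint8(rgb),
        label=label,
        patient_id=patient_id,
        tile_id=tile_id or f"{label}_{patient_id}_s{seed}",
        fiber_mask=f > 0.5,
    )


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic cohort (defaults mirror the study counts:
    280/240/216 tiles over 7/7/5 patients for FA/PTC/PTCFA)."""

    tiles_per_class: tuple[int, int, int] = (280, 240, 216)
    patients_per_class: tuple[int, int, int] = (7, 7, 5)
    tile_size: int = 1024
    class_effects: dict[str, FiberParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_EFFECTS)
    )
    noise_sd: float = 2.0
    patient_brightness_sd: float = 0.05  # SD of per-patient log10-OD scale
    tile_param_jitter: float = 0.15  # log-SD of per-tile texture variation
    tile_orientation_wobble_deg: float = 15.0  # per-tile direction wobble
    seed: int = 0
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        if len(self.tiles_per_class) != len(self.classes) or len(
            self.patients_per_class
        ) != len(self.classes):
            raise ValueError("per-class tuples must match the class list")
        if any(t < 0 for t in self.tiles_per_class):
            raise ValueError("tile counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for t, p in zip(self.tiles_per_class, self.patients_per_class):
            if t > 0 and p < 1:
                raise ValueError("a class with tiles needs at least one patient")
        missing = [c for c in self.classes if c not in self.class_effects]
        if missing:
            raise ValueError(f"missing class effects for {missing}")


def make_cohort(spec: CohortSpec) -> list[RGBTile]:
    """Generate the full labeled cohort described by ``spec``.

    Tiles are distributed as evenly as possible over each class's patients,
    with any remainder going to the lowest-indexed patients.  Every patient
    receives a multiplicative brightness offset (log-normal on the OD
    scale), and every tile a log-normal jitter of its texture parameters
    plus a wobble of the dominant fiber direction — regions of interest on
    a real slide never repeat the same texture exactly.  The seed fully
    determines the output.
    """
    rng = np.random.default_rng(spec.seed)
    tiles: list[RGBTile] = []
    for label, n_tiles, n_pat in zip(
        spec.classes, spec.tiles_per_class, spec.patients_per_class
    ):
        base_params = dataclasses.replace(
            spec.class_effects[label], noise_sd=spec.noise_sd
        )
        offsets = rng.normal(0.0, spec.patient_brightness_sd, n_pat)
        per_pat, rem = divmod(n_tiles, n_pat) if n_pat else (0, 0)
        for pi in range(n_pat):
            patient_id = f"{label}_P{pi + 1:02d}"
            scale = float(np.exp(offsets[pi]))
            params = dataclasses.replace(
                base_params,
                hematoxylin_od=base_params.hematoxylin_od * scale,
                eosin_od=base_params.eosin_od * scale,
            )
            count = per_pat + (1 if pi < rem else 0)
            for ti in range(count):
                jitter = np.exp(rng.normal(0.0, spec.tile_param_jitter, 3))
                wobble = rng.uniform(
                    -spec.tile_orientation_wobble_deg,
                    spec.tile_orientation_wobble_deg,
                )
                tile_params = dataclasses.replace(
                    params,
                    od_contrast=params.od_contrast * jitter[0],
                    wavelength=params.wavelength * jitter[1],
                    waviness=params.waviness * jitter[2],
                    orientation_deg=params.orientation_deg + wobble,
                )
                tile_seed = int(rng.integers(0, 2**31 - 1))
                tiles.append(
                    make_fiber_tile(
                        spec.tile_size,
                        tile_params,
                        seed=tile_seed,
                        label=label,
                        patient_id=patient_id,
                        tile_id=f"{patient_id}_T{ti + 1:04d}",
                    )
                )
    return tiles


def _center_crop(tile: RGBTile, out_size: int, suffix: str) -> RGBTile:
    start = (tile.size - out_size) // 2
    stop = start + out_size
    mask = tile.fiber_mask
    return RGBTile(
        tile.pixels[start:stop, start:stop].copy(),
        label=tile.label,
        patient_id=tile.patient_id,
        tile_id=f"{tile.tile_id}{suffix}",
        fiber_mask=None if mask is None else mask[start:stop, start:stop].copy(),
    )


def crop_nested(tile: RGBTile) -> tuple[RGBTile, RGBTile]:
    """Centered 512 crop of a 1024 tile, and the centered 256 crop of that.

    Pure restrictions of the pixel grid — no resampling.  Relative to the
    1024 parent the 512 crop spans rows/cols [256, 768) and the 256 crop
    [384, 640).
    """
    if tile.size != 1024:
        raise ValueError("nested cropping expects a 1024 x 1024 tile")
    t512 = _center_crop(tile, 512, "@512")
    t256 = _center_crop(t512, 256, "@256")
    t256.tile_id = f"{tile.tile_id}@256"
    return t512, t256


def write_cohort(
    tiles, outdir: str | Path, fmt: str = "png"
) -> pd.DataFrame:
    """Write tiles as 8-bit RGB images plus a manifest CSV.

    Returns the manifest (columns tile_id, path, label, patient_id, size);
    it is also written to ``outdir/manifest.csv``.
    """
    from PIL import Image

    if fmt not in ("png", "tiff"):
        raise ValueError("format must be 'png' or 'tiff'")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for tile in tiles:
        path = outdir / f"{tile.tile_id}.{fmt}"
        if fmt == "png":
            Image.fromarray(tile.pixels, mode="RGB").save(path)
        else:
            import tifffile

            tifffile.imwrite(path, tile.pixels, photometric="rgb")
        records.append(
            {
                "tile_id": tile.tile_id,
                "path": str(path),
                "label": tile.label,
                "patient_id": tile.patient_id,
                "size": tile.size,
            }
        )
    manifest = pd.DataFrame(
        records, columns=["tile_id", "path", "label", "patient_id", "size"]
    )
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest


def load_cohort(manifest_path: str | Path) -> list[RGBTile]:
    """Load tiles listed in a cohort manifest CSV."""
    from PIL import Image

    manifest = pd.read_csv(manifest_path)
    tiles = []
    for row in manifest.itertuples():
        pixels = np.asarray(Image.open(row.path).convert("RGB"))
        tiles.append(
            RGBTile(pixels, label=row.label, patient_id=row.patient_id, tile_id=row.tile_id)
        )
    return tiles
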