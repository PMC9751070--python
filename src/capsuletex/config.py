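"""Pipeline configuration: one flat TOML file drives the whole experiment.

Every stochastic stage derives its seed from the single master seed, so a
rerun with the same config reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .forest import DEFAULT_FRACTIONS, DEFAULT_TOP_N, DEFAULT_TREES
from .synthgen import CohortSpec

__all__ = ["PipelineConfig", "load_config", "save_config", "stage_seeds"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one experiment run needs, round-trippable through TOML."""

    tiles_per_class: tuple[int, int, int] = (280, 240, 216)
    patients_per_class: tuple[int, int, int] = (7, 7, 5)
    generate_size: int = 1024  # size tiles are rendered at
    analyze_size: int = 1024  # size features are computed on (nested crops)
    noise_sd: float = 2.0
    patient_brightness_sd: float = 0.05
    glcm_distance: int = 1
    glcm_levels: int = 256
    orientation_sigma: float = 2.0
    run_fisher: bool = True
    run_anova: bool = True
    run_baselines: bool = True
    trees: int = DEFAULT_TREES
    top_n: int = DEFAULT_TOP_N
    repeats: int = 10
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0
    outdir: str = "capsuletex_run"
    write_images: bool = False

    def __post_init__(self) -> None:
        if self.analyze_size not in (256, 512, 1024):
            raise ValueError("analyze_size must be one of 256, 512, 1024")
        if self.analyze_size > self.generate_size:
            raise ValueError("analyze_size cannot exceed generate_size")
        if self.analyze_size != self.generate_size and self.generate_size != 1024:
            raise ValueError("nested crops are defined for 1024-pixel parents")

    def cohort_spec(self, seed: int | None = None) -> CohortSpec:
        return CohortSpec(
            tiles_per_class=tuple(self.tiles_per_class),
            patients_per_class=tuple(self.patients_per_class),
            tile_size=self.generate_size,
            noise_sd=self.noise_sd,
            patient_brightness_sd=self.patient_brightness_sd,
            seed=self.seed if seed is None else seed,
        )


def stage_seeds(master: int) -> dict[str, int]:
    """Derive one independent sub-seed (< 2**31) per stochastic stage."""
    ss = np.random.SeedSequence(master)
    names = ("cohort", "splits", "forest", "baselines")
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint64)[0] % (2**31))
        for name, child in zip(names, children)
    }


_TUPLE_FIELDS = {"tiles_per_class", "patients_per_class", "fractions"}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {k: tuple(v) if k in _TUPLE_FIELDS else v for k, v in raw.items()}
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            lines.append(f"{f.name} = [{', '.join(repr(x) for x in v)}]")
        elif isinstance(v, bool):
            lines.append(f"{f.name} = {'true' if v else 'false'}")
        elif isinstance(v, str):
            lines.append(f'{f.name} = "{v}"')
        else:
            lines.append(f"{f.name} = {v}")
    Path(path).write_text("\n".join(lines) + "\n")
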