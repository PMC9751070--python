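"""End-to-end experiment orchestration: synthesize -> extract -> select ->
classify -> report, reproducible from one master seed."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, features, forest, selection, synthgen
from .config import PipelineConfig, save_config, stage_seeds

__all__ = ["RunBundle", "run_experiment", "report_tables"]

log = logging.getLogger("capsuletex")


@dataclass(eq=False)
class RunBundle:
    """Paths and in-memory artifacts of one completed experiment run."""

    config: PipelineConfig
    outdir: Path
    features: pd.DataFrame
    fisher: selection.FisherResult | None
    anova: pd.DataFrame | None
    reports: dict[str, forest.MetricsReport]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

        return inner

    return wrap


def run_experiment(config: PipelineConfig) -> RunBundle:
    """Execute all stages in order and write the artifact bundle.

    Writes ``manifest.csv`` (and tiles if configured), ``features.csv``,
    ``fisher.csv``, ``anova.csv``, ``report.json``, ``config.toml`` and a
    run log under ``config.outdir``.  Rerunning with the same config yields
    identical outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    _setup_log(outdir)
    log.info("capsuletex %s on %s", __version__, platform.python_version())
    log.info("stage seeds: %s", seeds)
    save_config(config, outdir / "config.toml")

    tiles = _stage("synthesize")(_synthesize)(config, seeds["cohort"], outdir)
    table_df = _stage("extract")(_extract)(config, tiles, outdir)
    fisher_res, anova_df = _stage("select")(_select)(config, table_df, outdir)
    reports = _stage("classify")(_classify)(config, table_df, seeds, outdir)

    bundle = RunBundle(config, outdir, table_df, fisher_res, anova_df, reports)
    (outdir / "summary.txt").write_text(report_tables(bundle))
    return bundle


def _setup_log(outdir: Path) -> None:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.setLevel(logging.INFO)
    log.addHandler(handler)


def _synthesize(config: PipelineConfig, seed: int, outdir: Path):
    spec = config.cohort_spec(seed=seed)
    tiles = synthgen.make_cohort(spec)
    if config.analyze_size != config.generate_size:
        cropped = []
        for t in tiles:
            t512, t256 = synthgen.crop_nested(t)
            cropped.append(t512 if config.analyze_size == 512 else t256)
        tiles = cropped
    log.info("synthesized %d tiles at %d px", len(tiles), config.analyze_size)
    if config.write_images:
        synthgen.write_cohort(tiles, outdir / "tiles")
    else:
        pd.DataFrame(
            {
                "tile_id": [t.tile_id for t in tiles],
                "path": "",
                "label": [t.label for t in tiles],
                "patient_id": [t.patient_id for t in tiles],
                "size": [t.size for t in tiles],
            }
        ).to_csv(outdir / "manifest.csv", index=False)
    return tiles


def _extract(config: PipelineConfig, tiles, outdir: Path) -> pd.DataFrame:
    cfg = features.FeatureConfig(
        glcm_distance=config.glcm_distance,
        glcm_levels=config.glcm_levels,
        orientation_sigma=config.orientation_sigma,
    )
    df = features.extract_table(tiles, cfg)
    df.to_csv(outdir / "features.csv", index=False)
    log.info("extracted %d x %d feature table", df.shape[0], df.shape[1] - 4)
    return df


def _select(config: PipelineConfig, df: pd.DataFrame, outdir: Path):
    if df.empty:
        return None, None
    table = selection.FeatureTable.from_dataframe(df)
    fisher_res = anova_df = None
    if config.run_fisher:
        fisher_res = selection.fisher_scores(table)
        selection.fisher_grid(fisher_res).to_csv(outdir / "fisher.csv")
        log.info(
            "fisher: %d/%d features above mean score %.4f",
            int(fisher_res.selected.sum()),
            len(fisher_res.scores),
            fisher_res.mean_score,
        )
    if config.run_anova:
        anova_df = selection.anova_table(table)
        anova_df.to_csv(outdir / "anova.csv", index=False)
        log.info("anova: %d/%d features significant after Holm",
                 int(anova_df["significant"].sum()), len(anova_df))
    return fisher_res, anova_df


def _classify(config: PipelineConfig, df: pd.DataFrame, seeds, outdir: Path):
    if df.empty:
        (outdir / "report.json").write_text(json.dumps({}))
        return {}
    table = selection.FeatureTable.from_dataframe(df)
    plans = forest.make_patient_splits(
        table, repeats=config.repeats, fractions=config.fractions, seed=seeds["splits"]
    )
    reports = {
        "Proposed": forest.run_repeated(
            table, plans, n_trees=config.trees, top_n=config.top_n, seed=seeds["forest"]
        )
    }
    if config.run_baselines:
        reports.update(forest.run_baselines(table, plans, seed=seeds["baselines"]))
    payload = {name: rep.to_dict() for name, rep in reports.items()}
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    log.info("classification report for %d method(s) written", len(reports))
    return reports


def report_tables(bundle: RunBundle) -> str:
    """Human-readable Fisher grid and metrics table for one run."""
    if bundle.features is None or bundle.features.empty:
        return "no data: the cohort is empty\n"
    lines = [f"capsuletex run ({bundle.outdir})", ""]
    if bundle.fisher is not None:
        lines += [
            "Fisher scores (mean threshold "
            f"{bundle.fisher.mean_score:.4f}; * = selected)",
            "",
        ]
        grid = selection.fisher_grid(bundle.fisher)
        score_cols = [c for c in grid.columns if not c.endswith("_selected")]
        shown = grid[score_cols].round(4).astype(str)
        for c in score_cols:
            stars = grid[f"{c}_selected"].map({True: "*", False: " "})
            shown[c] = shown[c] + stars
        lines.append(shown.to_string())
        lines.append("")
    if bundle.reports:
        rows = {}
        for method, rep in sorted(bundle.reports.items()):
            s = rep.summary()
            rows[method] = {
                f"{c}.{m}": f"{s.loc[c, m + '_mean']:.2f} ± {s.loc[c, m + '_sd']:.2f}"
                for c in rep.classes
                for m in ("f1", "recall", "precision")
            }
        lines.append("Classification (mean ± SD over repeated patient-level splits)")
        lines.append("")
        lines.append(pd.DataFrame(rows).T.to_string())
        lines.append("")
    return "\n".join(lines)
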