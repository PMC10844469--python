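"""End-to-end virtual experiments.

One virtual experiment mirrors one wet experiment: grow a culture, apply a
localized (dispensed) or uniform (bath) agonist stimulus, let cells respond
according to the ground-truth response model, calibrate the activation
cutoff on a resting companion sample, call activation, and summarize the
result spatially and statistically.  Everything is reproducible from the
configuration and its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .calling import CalibrationModel, ExperimentResult, call_activation, fit_cutoff, fraction_activated
from .config import PipelineConfig
from .diffusion import ConcentrationField
from .imaging import ImagePair, quantify_images, render_images
from .io import config_hash, write_cells, write_table
from .spatial import bin_fraction_activated, density_classify, neighbor_counts, radial_activation_profile
from .synthetic import draw_resting_ratios, generate_culture, simulate_response

__all__ = ["VirtualExperiment", "run_virtual_experiment", "replicate_panel"]

logger = logging.getLogger(__name__)


@dataclass
class VirtualExperiment:
    """Artifacts of one end-to-end virtual experiment."""

    config: PipelineConfig
    cells: pd.DataFrame
    calibration: CalibrationModel
    result: ExperimentResult
    radial_profile: pd.DataFrame
    bin_table: pd.DataFrame
    field: ConcentrationField | None
    images: ImagePair | None = None

    @property
    def density_class(self) -> str:
        return density_classify(self.cells, self.config.culture.area_mm2, self.config.spatial)


def _derived_seeds(seed: int, n: int = 5) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _merge_quantified(cells: pd.DataFrame, quantified: pd.DataFrame, tol_um: float = 5.0):
    """Replace generator ratios with image-derived ratios for matched cells."""
    if len(quantified) == 0 or len(cells) == 0:
        return cells
    tree = cKDTree(cells[["x_um", "y_um"]].to_numpy(float))
    q = quantified[~quantified["excluded"]].reset_index(drop=True)
    if len(q) == 0:
        return cells
    dist, idx = tree.query(q[["x_um", "y_um"]].to_numpy(float))
    out = cells.reset_index(drop=True)
    matched = dist <= tol_um
    rows = idx[matched]
    for col in ("nuc_intensity", "cyt_intensity", "nuc_cyt_ratio"):
        out.loc[rows, col] = q.loc[matched, col].to_numpy()
    return out


def run_virtual_experiment(config: PipelineConfig, outdir=None) -> VirtualExperiment:
    """Run one virtual experiment; optionally write all tables to ``outdir``."""
    seeds = _derived_seeds(config.seed)
    culture_cfg = replace(config.culture, seed=seeds[0])
    stage = "generate_culture"
    try:
        cells = generate_culture(culture_cfg, config.response, config.experiment_id)
        logger.info("generated %d cells at %g cells/mm^2", len(cells), culture_cfg.density)

        stage = "stimulus"
        if config.mode == "whole_culture":
            field = None
            stimulus = config.bath_conc_nM
        else:
            origin = (culture_cfg.field_width_um / 2.0, culture_cfg.field_height_um / 2.0)
            field = ConcentrationField(config.dispense, origin_um=origin)
            stimulus = field
            logger.info("dispensing field: C_max %.3g nM at %s", field.cmax_nM, origin)

        stage = "simulate_response"
        cells = simulate_response(
            cells,
            stimulus,
            config.t_stim_min,
            config.response,
            seed=seeds[1],
            density=culture_cfg.density,
        )

        images = None
        if config.render and len(cells):
            stage = "render_quantify"
            images = render_images(
                cells,
                seed=seeds[4],
                field_width_um=culture_cfg.field_width_um,
                field_height_um=culture_cfg.field_height_um,
            )
            cells = _merge_quantified(cells, quantify_images(images))

        stage = "calibration"
        resting = draw_resting_ratios(
            config.stats.calibration_n, config.response, np.random.default_rng(seeds[2])
        )
        calibration = fit_cutoff(resting)
        logger.info("activation cutoff %.4g (top %.0f%% of resting)", calibration.cutoff,
                    100 * (1 - calibration.quantile))

        stage = "call_activation"
        cells = call_activation(cells, calibration)
        cells = neighbor_counts(cells, config.spatial)

        stage = "statistics"
        condition = {
            "mode": config.mode,
            "t_stim_min": config.t_stim_min,
            "density_class": density_classify(cells, culture_cfg.area_mm2, config.spatial),
        }
        if field is not None:
            condition["cmax_nM"] = field.cmax_nM
        elif config.bath_conc_nM is not None:
            condition["bath_conc_nM"] = config.bath_conc_nM
        result = fraction_activated(cells, n_boot=config.stats.n_boot, seed=seeds[3],
                                    condition=condition)

        stage = "spatial_summaries"
        origin = field.origin_um if field is not None else (
            culture_cfg.field_width_um / 2.0, culture_cfg.field_height_um / 2.0
        )
        profile = radial_activation_profile(cells, origin, config.spatial.ring_width_um)
        bins = bin_fraction_activated(cells, config.spatial, field=field, origin_um=origin)
    except Exception as err:  # noqa: BLE001 - re-raise with stage tag
        raise RuntimeError(f"virtual experiment failed at stage {stage!r}: {err}") from err

    exp = VirtualExperiment(
        config=config,
        cells=cells,
        calibration=calibration,
        result=result,
        radial_profile=profile,
        bin_table=bins,
        field=field,
        images=images,
    )
    if outdir is not None:
        _write_outputs(exp, Path(outdir))
    return exp


def _write_outputs(exp: VirtualExperiment, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config_hash(exp.config), "seed": exp.config.seed}
    write_cells(exp.cells, outdir / "cells.csv", meta)
    write_table(exp.radial_profile, outdir / "radial_profile.csv", meta)
    write_table(exp.bin_table, outdir / "bins.csv", meta)
    exp.calibration.to_json(outdir / "calibration.json")
    summary = pd.DataFrame(
        [
            {
                "n_cells": exp.result.n_cells,
                "n_activated": exp.result.n_activated,
                "fraction_activated": exp.result.fraction_activated,
                "bootstrap_se": exp.result.bootstrap_se,
                "ci_low": exp.result.ci_low,
                "ci_high": exp.result.ci_high,
                "density_class": exp.density_class,
                **exp.result.condition,
            }
        ]
    )
    write_table(summary, outdir / "summary.csv", meta)
    if exp.images is not None:
        exp.images.to_tiff(outdir / "images.tiff")


def replicate_panel(
    config: PipelineConfig,
    n_replicates: int,
    seeds: list[int] | None = None,
    outdir=None,
) -> tuple[pd.DataFrame, ExperimentResult]:
    """Independent virtual experiments with per-replicate and pooled summaries.

    Returns (per-replicate table, pooled ExperimentResult over all cells).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    if seeds is None:
        seeds = _derived_seeds(config.seed, n_replicates)
    if len(seeds) != n_replicates:
        raise ValueError("seeds must match n_replicates")
    if len(set(seeds)) != len(seeds):
        logger.warning("duplicate seeds in replicate panel: replicates are not independent")

    rows = []
    all_calls = []
    for i, seed in enumerate(seeds):
        exp = run_virtual_experiment(replace(config, seed=int(seed)))
        res = exp.result
        rows.append(
            {
                "replicate": i,
                "seed": int(seed),
                "n_cells": res.n_cells,
                "n_activated": res.n_activated,
                "fraction_activated": res.fraction_activated,
                "bootstrap_se": res.bootstrap_se,
                "density_class": exp.density_class,
            }
        )
        all_calls.append(exp.cells["called"].to_numpy(dtype=bool))
    table = pd.DataFrame(rows)
    pooled_calls = np.concatenate(all_calls) if all_calls else np.array([], dtype=bool)
    pooled = fraction_activated(
        pooled_calls,
        n_boot=config.stats.n_boot,
        seed=config.seed,
        condition={"mode": config.mode, "t_stim_min": config.t_stim_min, "pooled": True},
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_table(table, out / "panel.csv", {"config_hash": config_hash(config)})
    return table, pooled
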