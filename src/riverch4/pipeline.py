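"""End-to-end orchestration: simulate -> screen -> train -> predict ->
upscale -> scenarios, with a reproducibility manifest.

Every stage logs its row counts; rerunning with the same config produces
byte-identical output tables (all randomness is derived from the config
seed and no timestamps enter the outputs).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import riverch4
from riverch4 import ensemble as ens
from riverch4 import scenarios as scn
from riverch4 import screening, synth, tables, upscaling
from riverch4.config import PipelineConfig
from riverch4.errors import ConfigError
from riverch4.synth import (
    IMPACTED_CLASSES,
    NUTRIENTS,
    TERRESTRIAL_PREDICTORS,
    TruthParams,
    VALID_LANDSCAPE_CLASSES,
)

log = logging.getLogger("riverch4")

#: Strict threshold for the density-based human-impact rule (people km^-2).
DENSITY_THRESHOLD = 20.0


def classify_human_impacted(landscape_class: str, population_density: float) -> bool:
    """True iff urban, cropland, or population density > 20 people km^-2."""
    if landscape_class not in VALID_LANDSCAPE_CLASSES:
        raise ValueError(f"unknown landscape class {landscape_class!r}")
    if landscape_class in IMPACTED_CLASSES:
        return True
    return population_density > DENSITY_THRESHOLD


def is_human_impacted(frame: pd.DataFrame) -> np.ndarray:
    """Vectorized :func:`classify_human_impacted` over a table."""
    bad = set(frame["landscape_class"]) - VALID_LANDSCAPE_CLASSES
    if bad:
        raise ValueError(f"unknown landscape classes: {sorted(bad)}")
    return (
        frame["landscape_class"].isin(IMPACTED_CLASSES)
        | (frame["population_density"] > DENSITY_THRESHOLD)
    ).to_numpy()


# ---------------------------------------------------------------------------
# Cell-month predictor construction
# ---------------------------------------------------------------------------


def cell_month_predictors(cells: pd.DataFrame, month: int) -> pd.DataFrame:
    """Predictor rows for every cell for one month.

    Nutrient concentrations come from that month's load/runoff ratio; water
    temperature is a deterministic seasonal offset of the cell's air
    temperature; terrestrial predictors are taken from the cell table.
    """
    out = cells[["cell_id", "country_id", "basin_id"]].copy()
    out["month"] = month
    for name in TERRESTRIAL_PREDICTORS:
        out[name] = cells[name].to_numpy(dtype=float)
    runoff = cells[f"runoff_m{month:02d}"].to_numpy(dtype=float)
    for species in NUTRIENTS:
        load = cells[f"load_{species.lower()}_m{month:02d}"].to_numpy(dtype=float)
        out[species] = upscaling.cell_nutrient_concentration(load, runoff)
    out["water_temp"] = (
        cells["air_temp"].to_numpy(dtype=float)
        + 2.0
        + 6.0 * np.cos(2.0 * np.pi * (month - 7) / 12.0)
    )
    return out


# ---------------------------------------------------------------------------
# Stage functions
# ---------------------------------------------------------------------------


def _truth_params(config: PipelineConfig) -> TruthParams:
    overrides = dict(config.truth)
    overrides.setdefault("seed", config.seed)
    return TruthParams.from_dict(overrides)


def stage_simulate(config: PipelineConfig, out: Path) -> dict[str, pd.DataFrame]:
    params = _truth_params(config)
    if config.observations_path:
        obs = tables.read_observations(config.observations_path)
    else:
        obs = synth.simulate_observations(config.n_sites, params)
    if config.reaches_path and config.cells_path:
        reaches = tables.read_reaches(config.reaches_path)
        cells = tables.read_cells(config.cells_path)
    else:
        reaches, cells = synth.generate_network(
            config.n_cells, config.reaches_per_cell, params
        )
    tables.write_observations(obs, out / "observations.csv")
    tables.write_reaches(reaches, out / "reaches.csv")
    tables.write_cells(cells, out / "cells.csv")
    tables.save_truth_params(params, out / "truth_params.yaml")
    log.info("simulate: %d observations, %d reaches, %d cells",
             len(obs), len(reaches), len(cells))
    return {"observations": obs, "reaches": reaches, "cells": cells}


def stage_screen(config: PipelineConfig, obs: pd.DataFrame, out: Path) -> pd.DataFrame:
    frames = [
        screening.global_coefficients(
            obs, min_n=config.subgroup_min_n, seed=config.seed
        )
    ]
    for grouping in config.groupings:
        frames.append(
            screening.subgroup_coefficients(
                obs, grouping, min_n=config.subgroup_min_n, seed=config.seed
            ).assign(grouping=grouping)
        )
    coeffs = pd.concat(frames, ignore_index=True)
    coeffs["grouping"] = coeffs.get("grouping", pd.Series(dtype=str)).fillna("global")
    tables.write_table(coeffs, out / "coefficients.csv")

    curve = screening.density_gradient_curve(
        obs,
        config.density_thresholds,
        span=config.loess_span,
        min_n=config.subgroup_min_n,
        seed=config.seed,
    )
    tables.write_table(curve, out / "density_gradient.csv")
    log.info("screen: %d coefficient records", len(coeffs))
    return coeffs


def stage_train(
    config: PipelineConfig, obs: pd.DataFrame, out: Path
) -> dict[tuple[str, int], ens.TrainedMonthlyEnsemble]:
    models: dict[tuple[str, int], ens.TrainedMonthlyEnsemble] = {}
    manifest = []
    for response in config.responses:
        for month in synth.MONTHS:
            model = ens.fit_monthly_ensemble(
                obs,
                month,
                response,
                predictors=config.predictors,
                log_predictors=config.log_predictors,
                seed=config.seed,
                min_n=config.min_window_n,
                test_fraction=config.test_fraction,
                learner_params=config.learner_params,
                grids=config.tuning_grids,
                tune_folds=config.tune_folds,
            )
            models[(response, month)] = model
            manifest.append(
                {
                    "response": response,
                    "month": month,
                    "seed": config.seed,
                    "predictors": list(model.predictors),
                    "log_predictors": list(model.log_predictors),
                    "chosen_params": model.chosen_params,
                    "n_train": int(len(model.train_index)),
                    "n_test": int(len(model.test_index)),
                    "holdout_r2": model.holdout_r2(),
                }
            )
    models_dir = out / "models"
    models_dir.mkdir(parents=True, exist_ok=True)
    with open(models_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    import joblib

    joblib.dump(models, models_dir / "ensembles.joblib")
    log.info("train: %d monthly ensembles", len(models))
    return models


def _predict_flux(
    models: Mapping[tuple[str, int], ens.TrainedMonthlyEnsemble],
    monthly_frames: Mapping[int, pd.DataFrame],
) -> pd.DataFrame:
    rows = []
    for month in synth.MONTHS:
        frame = monthly_frames[month]
        preds = ens.ensemble_predict(
            models[("ln_flux", month)], frame, output="natural", per_member=True
        )
        block = frame[["cell_id", "month"]].copy()
        block["flux"] = preds["ensemble"].to_numpy()
        for name in ens.LEARNER_NAMES:
            block[f"flux_{name}"] = preds[name].to_numpy()
        rows.append(block)
    return pd.concat(rows, ignore_index=True)


def stage_predict(
    config: PipelineConfig,
    models: Mapping[tuple[str, int], ens.TrainedMonthlyEnsemble],
    cells: pd.DataFrame,
    out: Path,
) -> pd.DataFrame:
    monthly = {m: cell_month_predictors(cells, m) for m in synth.MONTHS}
    predictions = _predict_flux(models, monthly)
    tables.write_table(predictions, out / "predictions.csv")
    log.info("predict: %d cell-month rows", len(predictions))
    return predictions


def _upscale(
    config: PipelineConfig,
    predictions: pd.DataFrame,
    reaches: pd.DataFrame,
    cells: pd.DataFrame,
    flux_column: str = "flux",
) -> upscaling.EmissionTable:
    preds = predictions[["cell_id", "month", flux_column]].rename(
        columns={flux_column: "flux"}
    )
    return upscaling.compute_emissions(
        preds,
        reaches,
        cells,
        edges=config.ebullition_density_edges,
        ratios=config.ebullition_ratios,
        extrapolate_orders=config.extrapolate_orders,
        leap=config.leap_year,
    )


def stage_upscale(
    config: PipelineConfig,
    predictions: pd.DataFrame,
    reaches: pd.DataFrame,
    cells: pd.DataFrame,
    out: Path,
) -> upscaling.EmissionTable:
    table = _upscale(config, predictions, reaches, cells)
    # member spread -> +/- uncertainty on the grand total
    member_totals = [
        _upscale(config, predictions, reaches, cells, f"flux_{name}").grand_total_tg
        for name in ens.LEARNER_NAMES
    ]
    table.meta["grand_total_tg"] = table.grand_total_tg
    table.meta["member_totals_tg"] = member_totals
    table.meta["uncertainty_tg"] = (max(member_totals) - min(member_totals)) / 2.0
    tables.write_table(table.cell_month, out / "emissions.csv")
    tables.write_table(table.cell_annual, out / "emissions_annual.csv")
    tables.write_table(table.regional, out / "regional_summary.csv")
    log.info("upscale: grand total %.6g Tg CH4/yr (+/- %.3g)",
             table.grand_total_tg, table.meta["uncertainty_tg"])
    return table


def stage_scenarios(
    config: PipelineConfig,
    models: Mapping[tuple[str, int], ens.TrainedMonthlyEnsemble],
    obs: pd.DataFrame,
    reaches: pd.DataFrame,
    cells: pd.DataFrame,
    current: upscaling.EmissionTable,
    out: Path,
) -> pd.DataFrame:
    monthly = {m: cell_month_predictors(cells, m) for m in synth.MONTHS}
    region_rows = []
    cell_rows = []
    for raw_spec in config.scenarios:
        spec_kwargs = dict(raw_spec)
        if spec_kwargs.get("kind") == "pristine" and not spec_kwargs.get("pristine_lookup"):
            spec_kwargs["pristine_lookup"] = scn.pristine_lookup_from_observations(
                obs, cells["basin_id"].unique()
            )
        spec = scn.ScenarioSpec(**spec_kwargs)
        modified = {}
        for month, frame in monthly.items():
            modified[month], _ = scn.apply_scenario(frame, spec)
        predictions = _predict_flux(models, modified)
        table = _upscale(config, predictions, reaches, cells)
        result = scn.mitigation(current, table)
        region_rows.append(result["per_region"].assign(scenario=spec.kind))
        cell_rows.append(result["per_cell"].assign(scenario=spec.kind))
        log.info("scenario %s: reduction %.6g Tg",
                 spec.kind, current.grand_total_tg - table.grand_total_tg)
    per_region = pd.concat(region_rows, ignore_index=True)
    per_cell = pd.concat(cell_rows, ignore_index=True)
    tables.write_table(per_region, out / "mitigation.csv")
    tables.write_table(per_cell, out / "mitigation_cells.csv")
    return per_region


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage in dependency order and write the run manifest.

    Returns the artifact directory.  Any stage failure propagates with the
    stage name prefixed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": riverch4.__version__,
        "stages": {},
    }

    def run_stage(name, fn, *args):
        try:
            return fn(*args)
        except ConfigError:
            raise
        except Exception as exc:  # annotate with stage provenance
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    data = run_stage("simulate", stage_simulate, config, out)
    obs, reaches, cells = data["observations"], data["reaches"], data["cells"]
    manifest["stages"]["simulate"] = {
        "observations": len(obs), "reaches": len(reaches), "cells": len(cells)
    }

    coeffs = run_stage("screen", stage_screen, config, obs, out)
    manifest["stages"]["screen"] = {"coefficients": len(coeffs)}

    models = run_stage("train", stage_train, config, obs, out)
    manifest["stages"]["train"] = {"models": len(models)}

    predictions = run_stage("predict", stage_predict, config, models, cells, out)
    manifest["stages"]["predict"] = {"rows": len(predictions)}

    emissions = run_stage(
        "upscale", stage_upscale, config, predictions, reaches, cells, out
    )
    manifest["stages"]["upscale"] = {
        "grand_total_tg": emissions.grand_total_tg,
        "uncertainty_tg": emissions.meta["uncertainty_tg"],
        "member_totals_tg": emissions.meta["member_totals_tg"],
    }

    mitigation_table = run_stage(
        "scenarios", stage_scenarios, config, models, obs, reaches, cells, emissions, out
    )
    manifest["stages"]["scenarios"] = {"rows": len(mitigation_table)}

    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
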