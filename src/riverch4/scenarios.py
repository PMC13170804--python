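"""Counterfactual nutrient-reduction scenarios and mitigation accounting.

Three scenario kinds:

``sustainable``
    country-specific reduction ratio applied to all four nutrient species
    (phosphorus reduced by the same ratio as nitrogen).
``half``
    all four nutrient concentrations halved; no parameters.
``pristine``
    nutrient concentrations replaced by per-basin pristine levels, with a
    global-median fallback for basins lacking a pristine lookup entry.

A scenario edits nutrient concentration columns only; mitigation is the
difference between current and scenario emission tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from riverch4.errors import ConfigError
from riverch4.synth import NUTRIENTS
from riverch4.upscaling import EmissionTable

SCENARIO_KINDS: tuple[str, ...] = ("sustainable", "half", "pristine")


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one counterfactual nutrient scenario."""

    kind: str
    country_reduction_ratio: Mapping[str, float] = field(default_factory=dict)
    pristine_lookup: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    default_ratio: float | None = None  # sustainable fallback for unlisted countries

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ConfigError(f"unknown scenario kind {self.kind!r}")
        for country, ratio in self.country_reduction_ratio.items():
            if not 0.0 <= ratio <= 1.0:
                raise ConfigError(f"reduction ratio for {country!r} outside [0, 1]")
        if self.default_ratio is not None and not 0.0 <= self.default_ratio <= 1.0:
            raise ConfigError("default_ratio outside [0, 1]")
        for basin, conc in self.pristine_lookup.items():
            for species, value in conc.items():
                if value < 0:
                    raise ConfigError(
                        f"pristine concentration {species} in basin {basin!r} < 0"
                    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        data = {
            "kind": self.kind,
            "country_reduction_ratio": dict(self.country_reduction_ratio),
            "pristine_lookup": {b: dict(c) for b, c in self.pristine_lookup.items()},
            "default_ratio": self.default_ratio,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
        return path


def apply_scenario(
    table: pd.DataFrame,
    spec: ScenarioSpec,
) -> tuple[pd.DataFrame, dict]:
    """Return a copy of ``table`` with the four nutrient columns modified.

    ``table`` holds one row per prediction unit with nutrient concentration
    columns TP/NH4N/TN/NO3N; the sustainable scenario additionally needs
    ``country_id``, the pristine scenario ``basin_id``.  All other columns
    are untouched.  The returned metadata records the scenario kind and any
    pristine-fallback basins.
    """
    missing = [n for n in NUTRIENTS if n not in table.columns]
    if missing:
        raise KeyError(f"table lacks nutrient columns: {missing}")
    out = table.copy()
    meta: dict = {"scenario": spec.kind, "fallback_basins": []}

    if spec.kind == "half":
        for species in NUTRIENTS:
            out[species] = out[species] * 0.5
        return out, meta

    if spec.kind == "sustainable":
        if "country_id" not in out.columns:
            raise KeyError("sustainable scenario needs a country_id column")
        ratios = np.empty(len(out))
        for i, country in enumerate(out["country_id"]):
            if country in spec.country_reduction_ratio:
                ratios[i] = spec.country_reduction_ratio[country]
            elif spec.default_ratio is not None:
                ratios[i] = spec.default_ratio
            else:
                raise ConfigError(f"no reduction ratio for country {country!r}")
        for species in NUTRIENTS:
            out[species] = out[species] * (1.0 - ratios)
        return out, meta

    # pristine
    if "basin_id" not in out.columns:
        raise KeyError("pristine scenario needs a basin_id column")
    if not spec.pristine_lookup:
        raise ConfigError("pristine scenario needs a non-empty pristine_lookup")
    # fallback: median across all basins per species
    fallback = {
        species: float(
            np.median([c[species] for c in spec.pristine_lookup.values() if species in c])
        )
        for species in NUTRIENTS
    }
    fallback_basins = set()
    for species in NUTRIENTS:
        values = np.empty(len(out))
        for i, basin in enumerate(out["basin_id"]):
            conc = spec.pristine_lookup.get(basin)
            if conc is not None and species in conc:
                values[i] = conc[species]
            else:
                values[i] = fallback[species]
                fallback_basins.add(basin)
        out[species] = values
    meta["fallback_basins"] = sorted(fallback_basins)
    return out, meta


def pristine_lookup_from_observations(
    observations: pd.DataFrame,
    basins,
) -> dict[str, dict[str, float]]:
    """Median nutrient concentrations of pristine-class observations,
    assigned to every basin (the synthetic world has no real basin
    geography, so the global pristine median stands in per basin)."""
    pristine = observations.loc[observations["landscape_class"] == "pristine"]
    if pristine.empty:
        raise ConfigError("no pristine observations to build the lookup from")
    medians = {s: float(pristine[s].median()) for s in NUTRIENTS}
    return {str(b): dict(medians) for b in basins}


def mitigation(
    current: EmissionTable,
    scenario: EmissionTable,
) -> dict[str, pd.DataFrame]:
    """Absolute and percentage emission reduction per cell and per region.

    Both tables must cover identical cell sets (and hence masking).
    """
    cur = current.cell_annual.set_index("cell_id")
    scn = scenario.cell_annual.set_index("cell_id")
    if set(cur.index) != set(scn.index):
        raise ValueError("mismatched cell sets between current and scenario tables")
    scn = scn.loc[cur.index]

    per_cell = pd.DataFrame(
        {
            "cell_id": cur.index,
            "current_g": cur["total_g"].to_numpy(),
            "scenario_g": scn["total_g"].to_numpy(),
        }
    )
    per_cell["reduction_g"] = per_cell["current_g"] - per_cell["scenario_g"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * per_cell["reduction_g"] / per_cell["current_g"]
    per_cell["percent"] = pct.fillna(0.0)

    cur_reg = current.regional.set_index(["region_type", "region"])
    scn_reg = scenario.regional.set_index(["region_type", "region"])
    scn_reg = scn_reg.reindex(cur_reg.index)
    per_region = pd.DataFrame(
        {
            "current_tg": cur_reg["total_tg"],
            "scenario_tg": scn_reg["total_tg"],
        }
    )
    per_region["reduction_tg"] = per_region["current_tg"] - per_region["scenario_tg"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * per_region["reduction_tg"] / per_region["current_tg"]
    per_region["percent"] = pct.fillna(0.0)
    per_region = per_region.reset_index()
    return {"per_cell": per_cell, "per_region": per_region}
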