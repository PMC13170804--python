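"""Synthetic observation / reach / grid-cell generator with a known truth.

Every downstream stage (screening, ensemble modelling, upscaling,
scenarios) is testable by parameter recovery against the generative
coefficients held in :class:`TruthParams`.  The generator emulates the
schema of a site-level CH4 measurement database, a river-reach hydrography
table and a 0.5-degree grid-cell nutrient/runoff table, without any attempt
at real geography.

All randomness flows from ``TruthParams.seed`` through
``numpy.random.default_rng`` seed sequences, so identical params yield
bit-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from riverch4.errors import ConfigError

# ---------------------------------------------------------------------------
# Vocabularies and schema constants
# ---------------------------------------------------------------------------

#: 16 terrestrial reach-scale predictors (14 standard + 2 extra slots).
TERRESTRIAL_PREDICTORS: tuple[str, ...] = (
    "slope",
    "elevation",
    "soil_sand",
    "soil_ph",
    "soc",
    "population_density",
    "artificial_land",
    "cropland_cover",
    "gpp",
    "npp",
    "soil_respiration",
    "groundwater_table",
    "air_temp",
    "precipitation",
    "wetland_cover",
    "ndvi",
)

#: 5 aquatic predictors: four nutrient species plus water temperature.
AQUATIC_PREDICTORS: tuple[str, ...] = ("TP", "NH4N", "TN", "NO3N", "water_temp")

#: The four nutrient concentration fields, mg L^-1.
NUTRIENTS: tuple[str, ...] = ("TP", "NH4N", "TN", "NO3N")

ALL_PREDICTORS: tuple[str, ...] = TERRESTRIAL_PREDICTORS + AQUATIC_PREDICTORS

LANDSCAPE_CLASSES: tuple[str, ...] = ("urban", "cropland", "dense", "pristine")
#: Landscape classes that count as human-impacted regardless of density.
IMPACTED_CLASSES: frozenset[str] = frozenset({"urban", "cropland"})
#: Classes accepted by the classifier (generator only emits the first four).
VALID_LANDSCAPE_CLASSES: frozenset[str] = frozenset(
    {"urban", "cropland", "dense", "pristine", "forest", "grassland", "wetland"}
)

CLASS_PROBS: tuple[float, ...] = (0.20, 0.30, 0.20, 0.30)

CLIMATE_ZONES: tuple[str, ...] = ("tropical", "arid", "temperate", "boreal")
CONTINENTS: tuple[str, ...] = (
    "Africa",
    "Asia",
    "Europe",
    "North America",
    "Oceania",
    "South America",
)
INCOME_GROUPS: tuple[str, ...] = ("low", "lower-middle", "upper-middle", "high")

#: Pristine-river baseline nutrient levels (mg L^-1) and ln-scale spread.
NUTRIENT_BASELINE: dict[str, float] = {
    "TP": 0.02,
    "NH4N": 0.02,
    "TN": 0.50,
    "NO3N": 0.20,
}
NUTRIENT_LOG_SD: float = 1.0

# mean / sd used for terrestrial predictor draws (population_density and
# air_temp handled specially).
_TERRESTRIAL_DRAWS: dict[str, tuple[float, float]] = {
    "slope": (5.0, 2.0),
    "elevation": (400.0, 300.0),
    "soil_sand": (50.0, 15.0),
    "soil_ph": (6.5, 0.8),
    "soc": (40.0, 15.0),
    "artificial_land": (0.10, 0.08),
    "cropland_cover": (0.30, 0.20),
    "gpp": (1200.0, 400.0),
    "npp": (600.0, 200.0),
    "soil_respiration": (700.0, 250.0),
    "groundwater_table": (10.0, 5.0),
    "precipitation": (900.0, 400.0),
    "wetland_cover": (0.05, 0.05),
    "ndvi": (0.5, 0.2),
}

MONTHS = tuple(range(1, 13))


# ---------------------------------------------------------------------------
# Truth parameters
# ---------------------------------------------------------------------------


def _default_multipliers() -> dict[str, float]:
    return {"urban": 8.0, "cropland": 5.0, "dense": 4.0, "pristine": 1.0}


@dataclass(frozen=True)
class TruthParams:
    """Ground-truth generative coefficients for the synthetic world.

    ``ln(diff_flux) = intercept + beta_log_tp*ln(TP) + beta_log_nh4*ln(NH4N)
    + beta_log_tn*ln(TN) + beta_log_no3*ln(NO3N) + beta_temp*water_temp
    + sum(terrestrial_betas[k] * value_k) + Normal(0, noise_sd)``

    ``ln(ch4_conc)`` follows the same form with its own coefficients
    (``conc_betas`` when given, else ``conc_scale`` times the flux betas).
    """

    intercept: float = -1.5
    beta_log_tp: float = 0.45
    beta_log_nh4: float = 0.30
    beta_log_tn: float = 0.0
    beta_log_no3: float = 0.0
    beta_temp: float = 0.03
    terrestrial_betas: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 0.6

    conc_intercept: float = 0.4
    conc_scale: float = 0.8
    conc_betas: Mapping[str, float] | None = None
    conc_noise_sd: float = 0.6

    enrichment_multipliers: Mapping[str, float] = field(
        default_factory=_default_multipliers
    )
    #: Upper edges of the population-density groups (people km^-2); the last
    #: group is open-ended.  len(ratios) == len(edges) + 1.
    ebullition_density_edges: tuple[float, ...] = (20.0, 200.0)
    ebullition_ratios: tuple[float, ...] = (0.15, 0.40, 0.80)

    #: Fraction of reach-months flagged inactive (dry or ice-covered).
    inactive_fraction: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.conc_noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if any(m <= 0 for m in self.enrichment_multipliers.values()):
            raise ConfigError("enrichment multipliers must be > 0")
        if any(r < 0 for r in self.ebullition_ratios):
            raise ConfigError("ebullition ratios must be >= 0")
        if len(self.ebullition_ratios) != len(self.ebullition_density_edges) + 1:
            raise ConfigError(
                "need exactly len(edges) + 1 ebullition ratios "
                f"(got {len(self.ebullition_ratios)} ratios for "
                f"{len(self.ebullition_density_edges)} edges)"
            )
        if list(self.ebullition_density_edges) != sorted(
            self.ebullition_density_edges
        ):
            raise ConfigError("ebullition density edges must be increasing")
        if not 0 <= self.inactive_fraction <= 1:
            raise ConfigError("inactive_fraction must be in [0, 1]")
        for cls in self.enrichment_multipliers:
            if cls not in LANDSCAPE_CLASSES:
                raise ConfigError(f"unknown landscape class {cls!r}")

    # -- derived coefficient dictionaries ---------------------------------

    @property
    def flux_betas(self) -> dict[str, float]:
        """Coefficients of the ln diffusive-flux surface, keyed by term."""
        betas = {
            "log_TP": self.beta_log_tp,
            "log_NH4N": self.beta_log_nh4,
            "log_TN": self.beta_log_tn,
            "log_NO3N": self.beta_log_no3,
            "temp": self.beta_temp,
        }
        betas.update(self.terrestrial_betas)
        return betas

    @property
    def concentration_betas(self) -> dict[str, float]:
        if self.conc_betas is not None:
            return dict(self.conc_betas)
        return {k: self.conc_scale * v for k, v in self.flux_betas.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["terrestrial_betas"] = dict(self.terrestrial_betas)
        d["enrichment_multipliers"] = dict(self.enrichment_multipliers)
        d["ebullition_density_edges"] = list(self.ebullition_density_edges)
        d["ebullition_ratios"] = list(self.ebullition_ratios)
        if self.conc_betas is not None:
            d["conc_betas"] = dict(self.conc_betas)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TruthParams":
        kwargs = dict(d)
        for key in ("ebullition_density_edges", "ebullition_ratios"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def density_group(density: float, edges: Sequence[float]) -> int:
    """Index of the population-density group for ``density``.

    Groups are ``[0, edges[0]], (edges[0], edges[1]], ..., (edges[-1], inf)``.
    """
    if not np.isfinite(density) or density < 0:
        raise ConfigError(f"population density {density!r} matches no group")
    return int(np.searchsorted(np.asarray(edges, dtype=float), density, side="left"))


# ---------------------------------------------------------------------------
# Observation simulation
# ---------------------------------------------------------------------------


def _draw_density(rng: np.random.Generator, landscape_class: str) -> float:
    """Class-conditional population density so the >20 people/km2 rule for
    the 'dense' class is self-consistent and 'pristine' stays below it."""
    if landscape_class == "urban":
        return float(rng.lognormal(np.log(2000.0), 0.7))
    if landscape_class == "cropland":
        return float(rng.lognormal(np.log(80.0), 0.8))
    if landscape_class == "dense":
        return 20.0 + float(rng.lognormal(np.log(60.0), 0.8))
    # pristine: bounded away from the >20 threshold
    return min(float(rng.lognormal(np.log(3.0), 1.0)), 19.9)


def _seasonal_temp(month: np.ndarray, base: float = 15.0, amp: float = 8.0) -> np.ndarray:
    return base + amp * np.cos(2.0 * np.pi * (month - 7) / 12.0)


def _linear_response(
    intercept: float,
    betas: Mapping[str, float],
    ln_nutrients: Mapping[str, np.ndarray],
    water_temp: np.ndarray,
    terrestrial: Mapping[str, np.ndarray],
) -> np.ndarray:
    out = np.full_like(water_temp, intercept, dtype=float)
    for species in NUTRIENTS:
        out += betas.get(f"log_{species}", 0.0) * ln_nutrients[species]
    out += betas.get("temp", 0.0) * water_temp
    for name, beta in betas.items():
        if name.startswith("log_") or name == "temp":
            continue
        out += beta * np.asarray(terrestrial[name], dtype=float)
    return out


def simulate_observations(
    n_sites: int,
    params: TruthParams,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate ``n_sites`` site-level CH4 observations.

    Returns a table with one row per site: landscape class, population
    density, month, the four nutrient concentrations (class-specific
    log-normal), further aquatic covariates, the 16 terrestrial predictors,
    and CH4 concentration / diffusive flux produced by the truth surface.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if rng is None:
        rng = np.random.default_rng([params.seed, 1])

    classes = rng.choice(LANDSCAPE_CLASSES, size=n_sites, p=CLASS_PROBS)
    density = np.array([_draw_density(rng, c) for c in classes])
    month = rng.integers(1, 13, size=n_sites)
    continent = rng.choice(CONTINENTS, size=n_sites)

    mult = np.array([params.enrichment_multipliers[c] for c in classes])
    ln_nutrients: dict[str, np.ndarray] = {}
    for species in NUTRIENTS:
        loc = np.log(NUTRIENT_BASELINE[species] * mult)
        ln_nutrients[species] = rng.normal(loc, NUTRIENT_LOG_SD)

    water_temp = _seasonal_temp(month.astype(float)) + rng.normal(0, 3.0, n_sites)

    terrestrial: dict[str, np.ndarray] = {}
    for name, (mu, sd) in _TERRESTRIAL_DRAWS.items():
        vals = rng.normal(mu, sd, n_sites)
        if name in ("artificial_land", "cropland_cover", "wetland_cover", "ndvi"):
            vals = np.clip(vals, 0.0, 1.0)
        elif name in ("precipitation", "gpp", "npp", "soil_respiration", "soc",
                      "slope", "soil_sand"):
            vals = np.clip(vals, 0.0, None)
        terrestrial[name] = vals
    terrestrial["population_density"] = density
    terrestrial["air_temp"] = water_temp - 2.0 + rng.normal(0, 1.5, n_sites)

    ln_flux = _linear_response(
        params.intercept, params.flux_betas, ln_nutrients, water_temp, terrestrial
    )
    if params.noise_sd > 0:
        ln_flux = ln_flux + rng.normal(0, params.noise_sd, n_sites)
    ln_conc = _linear_response(
        params.conc_intercept,
        params.concentration_betas,
        ln_nutrients,
        water_temp,
        terrestrial,
    )
    if params.conc_noise_sd > 0:
        ln_conc = ln_conc + rng.normal(0, params.conc_noise_sd, n_sites)

    df = pd.DataFrame(
        {
            "site_id": [f"S{i:05d}" for i in range(n_sites)],
            "continent_label": continent,
            "landscape_class": classes,
            "population_density": density,
            "month": month,
        }
    )
    for species in NUTRIENTS:
        df[species] = np.exp(ln_nutrients[species])
    df["DOC"] = rng.lognormal(np.log(4.0), 0.6, n_sites)
    df["DO"] = np.clip(rng.normal(9.0, 1.5, n_sites), 0.1, None)
    df["water_temp"] = water_temp
    df["pH"] = rng.normal(7.6, 0.5, n_sites)
    df["chl_a"] = rng.lognormal(np.log(5.0), 0.9, n_sites)
    for name in TERRESTRIAL_PREDICTORS:
        if name in ("population_density",):
            continue  # already present as the record's density
        df[name] = terrestrial[name]
    df["ch4_conc"] = np.exp(ln_conc)
    df["diff_flux"] = np.exp(ln_flux)
    return df


def simulate_ebullition(
    diff_flux,
    population_density,
    params: TruthParams,
):
    """Ebullitive flux as a population-density-group ratio of diffusive flux.

    Scalar in/scalar out; arrays broadcast elementwise.
    """
    flux = np.asarray(diff_flux, dtype=float)
    if np.any(flux < 0):
        raise ValueError("diff_flux must be >= 0")
    dens = np.asarray(population_density, dtype=float)
    ratios = np.asarray(params.ebullition_ratios, dtype=float)
    if dens.ndim == 0:
        result = flux * ratios[density_group(float(dens), params.ebullition_density_edges)]
    else:
        groups = np.array(
            [density_group(d, params.ebullition_density_edges) for d in dens.ravel()]
        ).reshape(dens.shape)
        result = flux * ratios[groups]
    if result.ndim == 0:
        return float(result)
    return result


# ---------------------------------------------------------------------------
# Network / grid-cell generation
# ---------------------------------------------------------------------------

_ORDER_CHOICES = (2, 3, 4, 5, 6)  # order-1 streams left to extrapolation
_ORDER_PROBS = (0.38, 0.27, 0.17, 0.11, 0.07)


def _climate_zone(lat: float, rng: np.random.Generator) -> str:
    if abs(lat) < 23.5:
        return "tropical" if rng.random() > 0.2 else "arid"
    if abs(lat) < 50:
        return "temperate" if rng.random() > 0.15 else "arid"
    return "boreal"


def generate_network(
    n_cells: int,
    reaches_per_cell: int,
    params: TruthParams,
    *,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a reach table and its grid-cell table.

    Every reach references an existing cell; Strahler orders span at least
    three levels whenever there are >= 3 reaches; roughly
    ``params.inactive_fraction`` of reach-months are flagged inactive.
    """
    if n_cells < 1 or reaches_per_cell < 1:
        raise ValueError("n_cells and reaches_per_cell must be >= 1")
    if rng is None:
        rng = np.random.default_rng([params.seed, 2])

    months_f = np.arange(1, 13, dtype=float)
    season = 1.0 + 0.4 * np.sin(2.0 * np.pi * (months_f - 4) / 12.0)

    cell_rows = []
    for i in range(n_cells):
        lat = float(np.round(rng.uniform(-55, 70) * 2) / 2)
        row: dict = {
            "cell_id": f"C{i:05d}",
            "lat_band": lat,
            "climate_zone": _climate_zone(lat, rng),
            "continent": rng.choice(CONTINENTS),
            "income_group": rng.choice(INCOME_GROUPS),
            "country_id": f"K{rng.integers(0, 40):03d}",
            "basin_id": f"B{rng.integers(0, 12):03d}",
        }
        for name, (mu, sd) in _TERRESTRIAL_DRAWS.items():
            v = float(rng.normal(mu, sd))
            if name in ("artificial_land", "cropland_cover", "wetland_cover", "ndvi"):
                v = float(np.clip(v, 0.0, 1.0))
            elif name in ("precipitation", "gpp", "npp", "soil_respiration",
                          "soc", "slope", "soil_sand"):
                v = max(v, 0.0)
            row[name] = v
        # disturbance multiplier drives both the cell nutrient level and the
        # density of its reaches
        disturbance = float(rng.lognormal(np.log(3.0), 1.0))
        row["population_density"] = float(rng.lognormal(np.log(10.0 * disturbance), 0.5))
        row["air_temp"] = 20.0 - 0.35 * abs(lat) + float(rng.normal(0, 2.0))
        row["_disturbance"] = disturbance

        runoff_base = float(rng.lognormal(np.log(2.0e7), 0.8))
        runoff = runoff_base * season * rng.lognormal(0.0, 0.1, 12)
        for m in MONTHS:
            row[f"runoff_m{m:02d}"] = runoff[m - 1]
        for species in NUTRIENTS:
            conc = NUTRIENT_BASELINE[species] * disturbance * rng.lognormal(0.0, 0.4, 12)
            load = conc * runoff / 1000.0  # mg/L * m3 -> kg
            for m in MONTHS:
                row[f"load_{species.lower()}_m{m:02d}"] = load[m - 1]
        cell_rows.append(row)
    cells = pd.DataFrame(cell_rows)

    reach_rows = []
    rid = 0
    for _, cell in cells.iterrows():
        for _ in range(reaches_per_cell):
            order = int(rng.choice(_ORDER_CHOICES, p=_ORDER_PROBS))
            length = float(rng.lognormal(np.log(2000.0), 0.7))
            width_base = float(2.0 ** order * rng.lognormal(0.0, 0.3))
            widths = width_base * (1.0 + 0.15 * np.sin(2.0 * np.pi * (months_f - 4) / 12.0))
            dens = float(rng.lognormal(np.log(10.0 * cell["_disturbance"]), 0.6))
            if dens > 20.0:
                cls = str(rng.choice(("urban", "cropland", "dense"), p=(0.3, 0.4, 0.3)))
            else:
                cls = "pristine"
            active = (rng.random(12) >= params.inactive_fraction).astype(int)
            row = {
                "reach_id": f"R{rid:06d}",
                "grid_cell_id": cell["cell_id"],
                "length_m": length,
                "strahler_order": order,
                "population_density": dens,
                "landscape_class": cls,
            }
            for m in MONTHS:
                row[f"width_m{m:02d}"] = widths[m - 1]
            for m in MONTHS:
                row[f"active_m{m:02d}"] = int(active[m - 1])
            reach_rows.append(row)
            rid += 1
    reaches = pd.DataFrame(reach_rows)

    # guarantee the order span contract on small tables
    if len(reaches) >= 3 and reaches["strahler_order"].nunique() < 3:
        reaches.loc[reaches.index[:3], "strahler_order"] = [2, 3, 4]

    cells = cells.drop(columns=["_disturbance"])
    return reaches, cells


# ---------------------------------------------------------------------------
# Theoretical moments (used by recovery oracles)
# ---------------------------------------------------------------------------


def ln_nutrient_moments(params: TruthParams, species: str = "TP") -> tuple[float, float]:
    """Mean and variance of ln(species) under the generator's class mixture.

    The ln concentration is a mixture over landscape classes of
    ``Normal(ln(baseline * multiplier[class]), NUTRIENT_LOG_SD)`` with the
    fixed class probabilities; the mixture moments are closed-form.
    """
    locs = np.array(
        [
            np.log(NUTRIENT_BASELINE[species] * params.enrichment_multipliers[c])
            for c in LANDSCAPE_CLASSES
        ]
    )
    probs = np.array(CLASS_PROBS)
    mean = float(probs @ locs)
    var = float(NUTRIENT_LOG_SD**2 + probs @ (locs - mean) ** 2)
    return mean, var
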