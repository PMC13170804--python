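"""Grid-cell upscaling: nutrient concentrations from loads, monthly river
surface area with small-stream extrapolation and dry/ice masking, ebullition
addition, unit conversion and regional aggregation.

Units: fluxes in mmol CH4 m^-2 d^-1, areas in m^2, emissions in g CH4
(aggregates reported in Tg yr^-1).  Molar mass fixed at 16.04 g mol^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from riverch4.errors import ConfigError
from riverch4.synth import MONTHS, density_group

MOLAR_MASS_CH4 = 16.04  # g mol^-1

DAYS_IN_MONTH: tuple[int, ...] = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)
DAYS_IN_MONTH_LEAP: tuple[int, ...] = (31, 29, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

REGION_TYPES: tuple[str, ...] = ("climate_zone", "continent", "income_group")


def days_in_month(month: int, *, leap: bool = False) -> int:
    table = DAYS_IN_MONTH_LEAP if leap else DAYS_IN_MONTH
    return table[month - 1]


# ---------------------------------------------------------------------------
# Elementary conversions
# ---------------------------------------------------------------------------


def cell_nutrient_concentration(load_kg, runoff_m3, *, cell_id: str | None = None):
    """Nutrient concentration in mg L^-1 from a monthly load and runoff.

    ``kg / m^3 == g L^-1``, hence the factor 1000 to mg L^-1.
    """
    load = np.asarray(load_kg, dtype=float)
    runoff = np.asarray(runoff_m3, dtype=float)
    if np.any(runoff <= 0):
        where = f" in cell {cell_id}" if cell_id else ""
        raise ValueError(f"runoff must be > 0{where}")
    if np.any(load < 0):
        raise ValueError("nutrient load must be >= 0")
    out = 1000.0 * load / runoff
    return float(out) if out.ndim == 0 else out


def cell_monthly_emission(flux_mmol_m2_d, area_m2, days: int):
    """Monthly emission in g CH4 from flux, surface area and day count."""
    if days not in range(28, 32):
        raise ValueError(f"days must be in 28..31, got {days}")
    flux = np.asarray(flux_mmol_m2_d, dtype=float)
    area = np.asarray(area_m2, dtype=float)
    if np.any(flux < 0) or np.any(area < 0):
        raise ValueError("flux and area must be >= 0")
    out = flux * area * days * MOLAR_MASS_CH4 / 1000.0  # mmol -> mg -> g
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Surface area
# ---------------------------------------------------------------------------


def monthly_surface_area(reaches: pd.DataFrame, month: int) -> float:
    """Total active river surface area (m^2) of the given reaches for a month.

    Inactive (dry/ice-covered) reach-months contribute exactly 0.
    """
    if month not in range(1, 13):
        raise ValueError(f"month must be in 1..12, got {month}")
    width = reaches[f"width_m{month:02d}"].to_numpy(dtype=float)
    if np.any(width < 0):
        raise ValueError("negative reach width")
    active = reaches[f"active_m{month:02d}"].to_numpy(dtype=float)
    length = reaches["length_m"].to_numpy(dtype=float)
    return float(np.sum(width * length * active))


def strahler_extrapolate(
    area_by_order: Mapping[int, float],
    target_orders: Sequence[int],
) -> dict[int, float]:
    """Extrapolate river surface area to unmapped Strahler orders.

    Fits ln(area) on order by least squares over the observed orders and
    evaluates the fit at each target order.
    """
    observed = {int(o): float(a) for o, a in area_by_order.items() if a > 0}
    if len(observed) < 2:
        raise ValueError("need at least 2 observed orders with positive area")
    orders = np.array(sorted(observed))
    ln_area = np.log(np.array([observed[o] for o in orders]))
    fit = stats.linregress(orders.astype(float), ln_area)
    return {
        int(t): float(np.exp(fit.intercept + fit.slope * t)) for t in target_orders
    }


def surface_area_table(
    reaches: pd.DataFrame,
    *,
    extrapolate_orders: Sequence[int] = (),
) -> pd.DataFrame:
    """Per (cell, month) active surface area, optionally extrapolated.

    When ``extrapolate_orders`` is non-empty, a per-cell-month log-linear
    order/area fit adds area for those orders; cells/months with fewer than
    two positive observed orders fall back to the fit pooled over all cells
    for that month (and contribute nothing if that also fails).
    """
    rows = []
    for month in MONTHS:
        wcol, acol = f"width_m{month:02d}", f"active_m{month:02d}"
        eff = reaches[wcol] * reaches["length_m"] * reaches[acol]
        if np.any(reaches[wcol].to_numpy(dtype=float) < 0):
            raise ValueError("negative reach width")
        by_cell_order = (
            pd.DataFrame(
                {
                    "cell": reaches["grid_cell_id"],
                    "order": reaches["strahler_order"],
                    "area": eff,
                }
            )
            .groupby(["cell", "order"])["area"]
            .sum()
        )
        global_orders = by_cell_order.groupby("order").sum()
        global_fit: dict[int, float] = {}
        if extrapolate_orders:
            positive = global_orders[global_orders > 0]
            if len(positive) >= 2:
                global_fit = strahler_extrapolate(positive.to_dict(), extrapolate_orders)
        for cell in reaches["grid_cell_id"].unique():
            cell_areas = by_cell_order.loc[cell]
            direct = float(cell_areas.sum())
            extra = 0.0
            if extrapolate_orders:
                positive = cell_areas[cell_areas > 0]
                if len(positive) >= 2:
                    extra = sum(
                        strahler_extrapolate(positive.to_dict(), extrapolate_orders).values()
                    )
                elif global_fit:
                    # scale the pooled fit by the cell's share of direct area
                    total_direct = float(global_orders.sum())
                    share = direct / total_direct if total_direct > 0 else 0.0
                    extra = sum(global_fit.values()) * share
            rows.append(
                {"cell_id": cell, "month": month,
                 "area_m2": direct + extra, "area_direct_m2": direct}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Ebullition and aggregation
# ---------------------------------------------------------------------------


def add_ebullition(
    emissions: pd.DataFrame,
    density_by_cell: Mapping[str, float],
    edges: Sequence[float],
    ratios: Sequence[float],
) -> pd.DataFrame:
    """Add an ebullitive component from the population-density ratio table.

    ``emissions`` needs columns ``cell_id`` and ``diffusive_g``; the result
    gains ``ebullitive_g`` and ``total_g`` (total = diffusive * (1 + ratio)).
    """
    ratios = list(ratios)
    if len(ratios) != len(edges) + 1:
        raise ConfigError("need len(edges) + 1 ebullition ratios")
    out = emissions.copy()
    ratio_col = np.empty(len(out))
    for i, cell in enumerate(out["cell_id"]):
        if cell not in density_by_cell:
            raise ConfigError(f"no population density for cell {cell!r}")
        ratio_col[i] = ratios[density_group(density_by_cell[cell], edges)]
    out["ebullitive_g"] = out["diffusive_g"] * ratio_col
    out["total_g"] = out["diffusive_g"] + out["ebullitive_g"]
    return out


@dataclass
class EmissionTable:
    """Per-cell-month emissions with annual and regional rollups."""

    cell_month: pd.DataFrame  # cell_id, month, diffusive_g, ebullitive_g, total_g
    cell_annual: pd.DataFrame  # cell_id, *_g, total_tg
    regional: pd.DataFrame  # region_type, region, diffusive_tg, ebullitive_tg, total_tg
    meta: dict = field(default_factory=dict)

    @property
    def grand_total_tg(self) -> float:
        return float(self.cell_annual["total_tg"].sum())


def annual_aggregate(
    cell_month: pd.DataFrame,
    cells: pd.DataFrame,
    *,
    region_types: Sequence[str] = REGION_TYPES,
) -> EmissionTable:
    """Accumulate monthly cell emissions to annual and regional totals.

    Every cell must carry exactly the 12 months (masked months as zero
    rows) and a label for every region type.  Totals are converted from
    grams to Tg (1e12 g).
    """
    counts = cell_month.groupby("cell_id")["month"].agg(["count", "nunique"])
    bad = counts[(counts["count"] != 12) | (counts["nunique"] != 12)]
    if len(bad):
        raise ValueError(f"cells without exactly 12 monthly rows: {list(bad.index)[:5]}")
    if "ebullitive_g" not in cell_month.columns:
        cell_month = cell_month.assign(
            ebullitive_g=0.0, total_g=cell_month["diffusive_g"]
        )
    if (cell_month[["diffusive_g", "ebullitive_g"]].to_numpy() < 0).any():
        raise ValueError("emissions must be >= 0")

    annual = (
        cell_month.groupby("cell_id")[["diffusive_g", "ebullitive_g", "total_g"]]
        .sum()
        .reset_index()
    )
    annual["total_tg"] = annual["total_g"] / 1e12

    lookup = cells.set_index("cell_id")
    missing_cells = [c for c in annual["cell_id"] if c not in lookup.index]
    if missing_cells:
        raise ValueError(f"cells missing from cell table: {missing_cells[:5]}")

    regional_rows = []
    for region_type in region_types:
        if region_type not in lookup.columns:
            raise ValueError(f"cell table lacks region column {region_type!r}")
        labels = lookup.loc[annual["cell_id"], region_type]
        if labels.isna().any():
            raise ValueError(f"cells without a {region_type} label")
        grouped = annual.groupby(labels.to_numpy())[
            ["diffusive_g", "ebullitive_g", "total_g"]
        ].sum()
        for region, row in grouped.iterrows():
            regional_rows.append(
                {
                    "region_type": region_type,
                    "region": region,
                    "diffusive_tg": row["diffusive_g"] / 1e12,
                    "ebullitive_tg": row["ebullitive_g"] / 1e12,
                    "total_tg": row["total_g"] / 1e12,
                }
            )
    regional = pd.DataFrame(regional_rows)
    return EmissionTable(
        cell_month=cell_month.reset_index(drop=True),
        cell_annual=annual,
        regional=regional,
        meta={"molar_mass_g_mol": MOLAR_MASS_CH4},
    )


# ---------------------------------------------------------------------------
# End-to-end cell emission computation
# ---------------------------------------------------------------------------


def compute_emissions(
    predictions: pd.DataFrame,
    reaches: pd.DataFrame,
    cells: pd.DataFrame,
    *,
    edges: Sequence[float],
    ratios: Sequence[float],
    extrapolate_orders: Sequence[int] = (),
    leap: bool = False,
) -> EmissionTable:
    """Turn per-(cell, month) flux predictions into an EmissionTable.

    ``predictions`` needs columns ``cell_id``, ``month`` and ``flux``
    (mmol m^-2 d^-1).  The cell's population density for the ebullition
    lookup is the reach-length-weighted mean density of its reaches.
    """
    areas = surface_area_table(reaches, extrapolate_orders=extrapolate_orders)
    merged = predictions.merge(areas, on=["cell_id", "month"], how="left")
    if merged["area_m2"].isna().any():
        missing = merged.loc[merged["area_m2"].isna(), "cell_id"].unique()
        raise ValueError(f"no reach area for cells {list(missing)[:5]}")
    days = merged["month"].map(lambda m: days_in_month(int(m), leap=leap))
    merged["diffusive_g"] = [
        cell_monthly_emission(f, a, int(d))
        for f, a, d in zip(merged["flux"], merged["area_m2"], days)
    ]

    weights = reaches["length_m"]
    density_by_cell = (
        (reaches["population_density"] * weights).groupby(reaches["grid_cell_id"]).sum()
        / weights.groupby(reaches["grid_cell_id"]).sum()
    ).to_dict()
    with_eb = add_ebullition(
        merged[["cell_id", "month", "flux", "area_m2", "diffusive_g"]],
        density_by_cell,
        edges,
        ratios,
    )
    return annual_aggregate(with_eb, cells)
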