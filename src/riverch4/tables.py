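"""Delimited-table readers/writers for the three core tables.

Columns and units:

observations.csv
    site_id; continent_label; landscape_class; population_density
    (people km^-2); month (1-12); TP, NH4N, TN, NO3N, DOC, DO (mg L^-1);
    water_temp (deg C); pH; chl_a (ug L^-1); 15 further terrestrial
    predictor columns; ch4_conc (umol L^-1); diff_flux (mmol m^-2 d^-1).

reaches.csv
    reach_id; grid_cell_id; length_m (m); strahler_order; population_density
    (people km^-2); landscape_class; width_m01..width_m12 (m);
    active_m01..active_m12 (0/1; 0 = dry or ice-covered).

cells.csv
    cell_id; lat_band (deg); climate_zone; continent; income_group;
    country_id; basin_id; 16 terrestrial predictor columns;
    runoff_m01..runoff_m12 (m^3 month^-1);
    load_<species>_m01..m12 (kg month^-1) for tp, nh4n, tn, no3n.

Floats are written with full repr so tables round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from riverch4.synth import TruthParams


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    # shortest round-trip repr: read_csv restores bit-identical floats
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    # round_trip parser: restores exactly the floats written by write_table
    return pd.read_csv(path, float_precision="round_trip")


read_observations = read_table
read_reaches = read_table
read_cells = read_table


# keep dedicated writer names so callers read naturally
write_observations = write_table
write_reaches = write_table
write_cells = write_table


def save_truth_params(params: TruthParams, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=True)
    return path


def load_truth_params(path: str | Path) -> TruthParams:
    with open(path) as fh:
        return TruthParams.from_dict(yaml.safe_load(fh))
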