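"""Tabular I/O: plain CSV contracts, scenario files and the field workbook.

Column contracts (part of the public interface):

* raw analyzer stream — ``timestamp`` (ISO 8601), ``port`` (H0.5/H1.5/
  H3.0/REF1/REF2/REF3), ``wet_12ch4_ppb``, ``wet_13ch4_ppb``,
  ``h2o_percent``
* calibrated samples — ``timestamp``, ``height_m``, ``ch4_dry_ppb``,
  ``delta13c_obs_permil``, ``n_raw_points``
* daily Keeling fits — ``date``, ``height_m``, ``delta13c_mix_permil``,
  ``intercept_se_permil``, ``slope_permil_ppb``, ``r_squared``,
  ``n_points``, ``retained``
* kp table — ``date``, ``model_label``, ``kp``
* region table — ``region_id``, ``annual_ch4_emission``,
  ``delta_source_permil``
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .config import ScenarioConfig

PathLike = Union[str, Path]


def write_csv(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_raw_stream(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "port", "wet_12ch4_ppb", "wet_13ch4_ppb", "h2o_percent"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"raw stream missing columns {sorted(missing)}")
    return df


def read_calibrated(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    df["date"] = df["timestamp"].dt.normalize()
    return df


def read_daily_mix(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def read_kp_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["date"])
    missing = {"date", "model_label", "kp"} - set(df.columns)
    if missing:
        raise ValueError(f"kp table missing columns {sorted(missing)}")
    return df


def read_regions(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"region_id", "annual_ch4_emission", "delta_source_permil"} - set(df.columns)
    if missing:
        raise ValueError(f"region table missing columns {sorted(missing)}")
    return df


def read_ecosystem(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["date"])


def load_scenario(path: PathLike) -> ScenarioConfig:
    """Load a scenario from a flat YAML key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return ScenarioConfig(**data)


def save_scenario(config: ScenarioConfig, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(mode="json"), fh, sort_keys=True)
    return path


# Sheet/column mapping of the deposited field-campaign workbook.  The
# workbook ships observation and model-kp sheets; column headers are
# renamed to the internal contract on load.  Adjust the mapping here if
# a differently organized export is used.
WORKBOOK_SHEETS = {
    "calibrated": {
        "sheet": 0,
        "columns": {
            "time": "timestamp",
            "height": "height_m",
            "CH4": "ch4_dry_ppb",
            "d13C": "delta13c_obs_permil",
        },
    },
    "kp": {
        "sheet": "kp",
        "columns": {"time": "date", "model": "model_label", "kp": "kp"},
    },
}


def load_field_workbook(path: PathLike, kind: str = "calibrated") -> pd.DataFrame:
    """Load a sheet of the deposited field-campaign Excel workbook and
    rename its columns to the internal contract."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"field workbook not found at {path}; deposit the supplementary "
            "observation workbook there to run the observed-data pipeline"
        )
    layout = WORKBOOK_SHEETS[kind]
    df = pd.read_excel(path, sheet_name=layout["sheet"])
    df = df.rename(columns=layout["columns"])
    time_col = "timestamp" if "timestamp" in df else "date"
    if time_col in df:
        df[time_col] = pd.to_datetime(df[time_col])
    return df
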