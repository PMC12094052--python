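"""CSV readers/writers for the herd tables and pipeline artifacts.

All tables are plain CSV: ISO-8601 dates, 24-h clock, ``hour`` is the
integer start of the hourly bin in local time.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

SENSOR_COLUMNS = ["cow_id", "date", "hour", "rt_s", "et_s"]
EMISSION_COLUMNS = ["cow_id", "date", "hour", "ch4_g_d", "co2_g_d", "h2_g_d"]
PRODUCTION_COLUMNS = ["cow_id", "date", "dmi_kg", "refusal_dm_kg", "my_kg"]
TRUTH_COLUMNS = ["cow_id", "group", "parity", "dim"]


def _read(path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"cow_id": str, "date": str})
    except OSError as exc:
        raise OSError(f"failed reading {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df[required]


def read_sensor(path) -> pd.DataFrame:
    df = _read(path, SENSOR_COLUMNS)
    df["hour"] = df["hour"].astype(int)
    return df


def read_emissions(path) -> pd.DataFrame:
    df = _read(path, EMISSION_COLUMNS)
    df["hour"] = df["hour"].astype(int)
    return df


def read_production(path) -> pd.DataFrame:
    return _read(path, PRODUCTION_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    df = _read(path, TRUTH_COLUMNS)
    df["parity"] = df["parity"].astype(int)
    df["dim"] = df["dim"].astype(int)
    return df


def read_herd(directory) -> dict[str, pd.DataFrame]:
    """Read a fixture directory written by ``simulate.write_fixture``."""
    directory = Path(directory)
    out = {
        "sensor": read_sensor(directory / "sensor.csv"),
        "emissions": read_emissions(directory / "emissions.csv"),
        "production": read_production(directory / "production.csv"),
    }
    truth = directory / "truth.csv"
    if truth.exists():
        out["truth"] = read_truth(truth)
    return out
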