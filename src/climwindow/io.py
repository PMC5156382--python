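"""CSV/YAML serialization for analysis inputs and outputs.

Inputs are plain CSVs with a required header: climate tables carry a
``Date`` column (dd/mm/yyyy) plus one value column; biological tables carry
``Date``, a response column and optional covariate/group columns.  Model
sets round-trip through CSV with the window, dAICc, slope, standard error
and model-weight columns; every run can drop its fully-resolved config as
YAML next to its outputs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import RandomizationSet
from .timeframe import BiologicalTable, ClimateSeries, format_dates

__all__ = [
    "read_climate_csv", "read_biological_csv", "write_climate_csv", "write_biological_csv",
    "write_modelset_csv", "read_modelset_csv", "write_randomization_csv",
    "read_randomization_csv", "write_config_yaml",
]


def read_climate_csv(path, date_col: str = "Date", value_col: str | None = None) -> ClimateSeries:
    frame = pd.read_csv(path)
    if date_col not in frame.columns:
        raise ValueError(f"{path}: missing required column {date_col!r}")
    return ClimateSeries.from_frame(frame, date_col=date_col, value_col=value_col)


def write_climate_csv(series: ClimateSeries, path) -> None:
    pd.DataFrame({"Date": format_dates(series.dates), series.name: series.values}).to_csv(
        path, index=False)


def read_biological_csv(path, response: str, date_col: str = "Date",
                        covariates: list[str] | None = None,
                        group: str | None = None) -> BiologicalTable:
    frame = pd.read_csv(path)
    missing = [c for c in [date_col, response, *(covariates or []), *( [group] if group else [])]
               if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return BiologicalTable.from_frame(frame, response=response, date_col=date_col,
                                      covariates=covariates, group=group)


def write_biological_csv(biol: BiologicalTable, path) -> None:
    out = pd.DataFrame({"Date": format_dates(biol.dates),
                        biol.response_name: biol.response})
    if biol.covariates is not None:
        out = pd.concat([out, biol.covariates.reset_index(drop=True)], axis=1)
    if biol.group is not None:
        out["group"] = biol.group
    out.to_csv(path, index=False)


def write_modelset_csv(modelset, path) -> None:
    cols = [c for c in modelset.frame.columns if c != "note"] + ["note"]
    modelset.frame[cols].to_csv(path, index=False)


def read_modelset_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    if "note" in frame.columns:
        frame["note"] = frame["note"].fillna("")
    return frame


def write_randomization_csv(rand: RandomizationSet, path) -> None:
    rand.to_frame().to_csv(path, index=False)


def read_randomization_csv(path, kind: str = "sliding", cv: bool = False) -> RandomizationSet:
    frame = pd.read_csv(path)
    c = frame["c"].to_numpy() if "c" in frame.columns else None
    return RandomizationSet(frame["delta_aicc"].to_numpy(), c, kind=kind, cv=cv)


def _plain(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {f.name: _plain(getattr(value, f.name)) for f in dataclasses.fields(value)}
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, (tuple, list, np.ndarray)):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, Path):
        return str(value)
    return value


def write_config_yaml(config, path) -> None:
    """Serialize a run's fully-resolved configuration next to its outputs."""
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(config), fh, sort_keys=True)
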