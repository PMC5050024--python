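"""Trace containers and the plain-text CSV/TSV dialects.

ECS trace CSV: ``time_s, a505, a520, a535, irradiance_umol, phase`` with
``phase`` in {light, dark}.  Fluorescence trace CSV: ``time_s, fluor, event``
with ``event`` in {none, pulse_start, pulse_end, dark_start}.  Results tables
are TSV with ``#``-prefixed metadata header lines.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ECSTrace", "FluorTrace", "read_ecs_csv", "write_ecs_csv",
           "read_fluor_csv", "write_fluor_csv", "write_results_tsv"]

ECS_COLUMNS = ["time_s", "a505", "a520", "a535", "irradiance_umol", "phase"]
FLUOR_COLUMNS = ["time_s", "fluor", "event"]
FLUOR_EVENTS = {"none", "pulse_start", "pulse_end", "dark_start"}


@dataclass
class ECSTrace:
    """Three-wavelength absorbance time series with light-phase annotation."""

    data: pd.DataFrame
    chl_per_area: float

    def __post_init__(self) -> None:
        missing = [c for c in ECS_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"ECS trace missing columns {missing}")
        t = self.data["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data["time_s"].to_numpy(float)


@dataclass
class FluorTrace:
    """Fluorescence time series with saturation-pulse event markers."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FLUOR_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"fluorescence trace missing columns {missing}")
        bad = set(self.data["event"].unique()) - FLUOR_EVENTS
        if bad:
            raise ValueError(f"unknown fluorescence events {sorted(bad)}")


def write_ecs_csv(trace: ECSTrace, path: str | Path,
                  float_format: str | None = None) -> None:
    trace.data.to_csv(path, index=False, columns=ECS_COLUMNS,
                      float_format=float_format)


def read_ecs_csv(path: str | Path, chl_per_area: float) -> ECSTrace:
    df = pd.read_csv(path)
    return ECSTrace(df, chl_per_area=chl_per_area)


def write_fluor_csv(trace: FluorTrace, path: str | Path) -> None:
    trace.data.to_csv(path, index=False, columns=FLUOR_COLUMNS)


def read_fluor_csv(path: str | Path) -> FluorTrace:
    return FluorTrace(pd.read_csv(path))


def write_results_tsv(df: pd.DataFrame, path: str | Path,
                      meta: dict | None = None,
                      float_format: str = "%.6g") -> None:
    """Write a results table as TSV with '#'-prefixed provenance lines."""
    path = Path(path)
    lines = [f"# {k}: {v}" for k, v in (meta or {}).items()]
    body = df.to_csv(sep="\t", index=False, float_format=float_format)
    path.write_text("\n".join(lines) + ("\n" if lines else "") + body)
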