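"""Daily actinic-light schedules for phenotyping runs.

Three canonical day types are supported, mirroring a three-day screen:

* ``constant`` -- a single irradiance held for the whole photoperiod
  (growth-chamber conditions, 100 umol photons m^-2 s^-1 by default);
* ``sinusoidal`` -- a stepped multiplicative ramp from a dawn irradiance to a
  midday peak and back, one step per ``step_minutes``;
* ``fluctuating`` -- the sinusoidal baseline with every baseline interval
  interrupted by a 2x spike held 15 min followed by a 1.5x-of-baseline
  segment of 12 min, so that the midday spikes cycle through twice the
  sinusoidal peak.

A schedule is an ordered list of ``(start_time_s, irradiance)`` steps spanning
exactly one photoperiod; irradiance is piecewise constant between steps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["LightSchedule", "make_light_schedule", "read_schedule_csv",
           "write_schedule_csv"]

DAY_TYPES = ("constant", "sinusoidal", "fluctuating")

SPIKE_HOLD_S = 15 * 60      # 2x-of-baseline spike duration
SHOULDER_HOLD_S = 12 * 60   # subsequent 1.5x-of-baseline duration


@dataclass(frozen=True)
class LightSchedule:
    """Ordered piecewise-constant irradiance steps over one photoperiod."""

    steps: tuple[tuple[float, float], ...]  # (start_s, irradiance)
    photoperiod_h: float
    day_type: str

    def __post_init__(self) -> None:
        if self.photoperiod_h <= 0:
            raise ValueError("photoperiod must be positive")
        starts = np.array([s for s, _ in self.steps], float)
        irrs = np.array([i for _, i in self.steps], float)
        if starts.size == 0 or starts[0] != 0.0:
            raise ValueError("first step must begin at time 0")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("step start times must be strictly increasing")
        if np.any(irrs < 0):
            raise ValueError("irradiance must be >= 0")
        if starts[-1] >= self.span_s:
            raise ValueError("steps must lie within the photoperiod")

    @property
    def span_s(self) -> float:
        return self.photoperiod_h * 3600.0

    @property
    def peak_irradiance(self) -> float:
        return max(i for _, i in self.steps)

    def irradiance_at(self, t):
        """Irradiance at time(s) ``t`` seconds; zero outside the photoperiod."""
        t = np.asarray(t, float)
        starts = np.array([s for s, _ in self.steps], float)
        irrs = np.array([i for _, i in self.steps], float)
        idx = np.searchsorted(starts, t, side="right") - 1
        out = irrs[np.clip(idx, 0, len(irrs) - 1)]
        out = np.where((t < 0) | (t >= self.span_s), 0.0, out)
        return out if out.ndim else float(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["start_s", "irradiance_umol"])


def _sinusoidal_levels(start_irr: float, peak_irr: float,
                       photoperiod_h: float, step_minutes: float):
    """Levels and times of the stepped ramp; the peak is hit exactly.

    The multiplicative step ratio is r = (peak/start)^(1/n) with n the number
    of increments; the peak level is held across midday (two steps of each
    half-day) so the maximum irradiance is actually sampled.  For the default
    16 h / 30 min schedule this gives n = 14 and r ~= 1.20.
    """
    step_s = step_minutes * 60.0
    span_s = photoperiod_h * 3600.0
    per_half = int(round(span_s / 2.0 / step_s))
    n_up = per_half - 2
    if n_up < 1:
        raise ValueError("photoperiod too short for the requested step size")
    r = (peak_irr / start_irr) ** (1.0 / n_up)
    steps: list[tuple[float, float]] = []
    for i in range(n_up):                      # ascent
        steps.append((i * step_s, start_irr * r ** i))
    t_peak = n_up * step_s
    steps.append((t_peak, peak_irr))           # plateau spanning midday
    t_desc = span_s - n_up * step_s
    for i in range(n_up - 1, -1, -1):          # mirror descent
        steps.append((t_desc, start_irr * r ** i))
        t_desc += step_s
    return steps


def make_light_schedule(day_type: str, photoperiod_h: float = 16.0,
                        start_irr: float = 100.0, peak_irr: float | None = None,
                        step_minutes: float = 30.0) -> LightSchedule:
    """Build one of the three daily light schedules.

    ``start_irr`` is the constant level (constant day) or the dawn level
    (sinusoidal / fluctuating); ``peak_irr`` is the sinusoidal midday peak.
    The fluctuating day spikes to twice the instantaneous baseline, so its
    maximum is twice the sinusoidal peak.
    """
    if day_type not in DAY_TYPES:
        raise ValueError(f"unknown day_type {day_type!r}; expected one of {DAY_TYPES}")
    if photoperiod_h <= 0 or start_irr <= 0:
        raise ValueError("photoperiod and start irradiance must be positive")

    if day_type == "constant":
        return LightSchedule(((0.0, float(start_irr)),), photoperiod_h, day_type)

    if peak_irr is None or peak_irr <= 0:
        raise ValueError("peak_irr required for sinusoidal/fluctuating days")
    if peak_irr < start_irr:
        raise ValueError("peak irradiance below the dawn irradiance")

    base = _sinusoidal_levels(start_irr, peak_irr, photoperiod_h, step_minutes)
    if day_type == "sinusoidal":
        return LightSchedule(tuple(base), photoperiod_h, day_type)

    # fluctuating: split every baseline slot of step_minutes into
    # [2x for 15 min][1.5x for 12 min][baseline for the rest]
    step_s = step_minutes * 60.0
    if step_s < SPIKE_HOLD_S + SHOULDER_HOLD_S:
        raise ValueError("step_minutes too short for the spike pattern")
    span_s = photoperiod_h * 3600.0
    starts = [s for s, _ in base] + [span_s]
    steps: list[tuple[float, float]] = []
    for (t0, irr), t1 in zip(base, starts[1:]):
        t = t0
        while t < t1 - 1e-9:
            slot_end = min(t + step_s, t1)
            steps.append((t, 2.0 * irr))
            if t + SPIKE_HOLD_S < slot_end:
                steps.append((t + SPIKE_HOLD_S, 1.5 * irr))
            if t + SPIKE_HOLD_S + SHOULDER_HOLD_S < slot_end:
                steps.append((t + SPIKE_HOLD_S + SHOULDER_HOLD_S, irr))
            t = slot_end
    return LightSchedule(tuple(steps), photoperiod_h, day_type)


def write_schedule_csv(schedule: LightSchedule, path: str | Path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule_csv(path: str | Path, photoperiod_h: float,
                      day_type: str = "constant") -> LightSchedule:
    df = pd.read_csv(path)
    if list(df.columns) != ["start_s", "irradiance_umol"]:
        raise ValueError("schedule CSV must have columns start_s, irradiance_umol")
    steps = tuple(zip(df["start_s"].astype(float), df["irradiance_umol"].astype(float)))
    return LightSchedule(steps, photoperiod_h, day_type)
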