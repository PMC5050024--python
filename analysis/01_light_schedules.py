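#!/usr/bin/env python
"""Build the three daily light schedules and record their structure.

Day 1 is the constant growth-chamber condition (100 umol m^-2 s^-1), day 2 a
stepped sinusoidal ramp from 39 to 500, and day 3 the sinusoidal baseline
interrupted by 2x / 1.5x spikes so the midday fluctuations cycle through
1000 and 500 umol m^-2 s^-1.
"""

from pathlib import Path

from pmfield import make_light_schedule
from pmfield.schedules import write_schedule_csv

OUT = Path(__file__).resolve().parents[1] / "results" / "schedules"
OUT.mkdir(parents=True, exist_ok=True)

days = {
    "day1_constant": make_light_schedule("constant", 16.0, 100.0),
    "day2_sinusoidal": make_light_schedule("sinusoidal", 16.0, 39.0, 500.0),
    "day3_fluctuating": make_light_schedule("fluctuating", 16.0, 39.0, 500.0),
}
for name, sched in days.items():
    write_schedule_csv(sched, OUT / f"{name}.csv")
    irrs = [i for _, i in sched.steps]
    ratio = max((b / a for a, b in zip(irrs, irrs[1:]) if b > a), default=1.0)
    print(f"{name}: {len(sched.steps)} steps, dawn {irrs[0]:g}, "
          f"peak {sched.peak_irradiance:g} umol m^-2 s^-1, "
          f"max upward step ratio {ratio:.3g}")
print(f"wrote schedule CSVs to {OUT}")
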