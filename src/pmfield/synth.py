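"""Synthetic spectroscopy: pmf dynamics, ECS and fluorescence traces.

The generator embodies the mechanistic assumptions under test so that every
downstream estimator can be validated by round trip against known ground
truth:

* proton influx follows a saturating function of irradiance (throttled by the
  q_E feedback), efflux is ``g_H+ * pmf``, and the dark pmf is pinned by
  equilibration with the ATP pool;
* because the thylakoid membrane has a low electrical capacitance, newly
  deposited pmf appears first as electric field (dpsi) and then relaxes
  toward the steady-state dpsi/pmf partitioning with a single counter-ion
  time constant -- every upward light step therefore produces a transient
  dpsi "spike";
* the electrochromic shift (ECS) at 520 nm reports dpsi linearly; during a
  dark interval it decays first-order at g_H+ and inverts below the dark
  baseline by an amount proportional to the standing dpH;
* q_E is a Hill function of lumen pH, q_I grows with the damaged-PSII
  fraction, and photodamage accrues in proportion to the field-dependent
  S2QA- recombination rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ECSTrace, FluorTrace
from .params import PlantParams, NoiseModel
from .schedules import LightSchedule

__all__ = [
    "simulate_pmf_dynamics", "synthesize_ecs_trace",
    "synthesize_ecs_from_amplitudes", "synthesize_fluorescence_trace",
    "simulate_photoinhibition", "simulate_flash_ecs", "FlashPair",
    "fluorescence_levels",
]

PULSE_DURATION_S = 0.8  # saturation-pulse width emitted in fluorescence traces


# ---------------------------------------------------------------------------
# pmf dynamics
# ---------------------------------------------------------------------------

def simulate_pmf_dynamics(params: PlantParams, schedule: LightSchedule,
                          dt: float = 0.1, seed: int | None = None,
                          t_end: float | None = None) -> pd.DataFrame:
    """Integrate the two-compartment pmf model over a light schedule.

    Returns a frame with columns ``time_s, irradiance_umol, dpsi_mV, dpH_mV,
    pmf_mV, q_L, q_E``.  Integration uses an exponential (exact-relaxation)
    update per step, unconditionally stable for any ``dt``; ``dt`` should
    still resolve the schedule's steps.  ``seed`` is accepted for interface
    symmetry; the dynamics themselves are deterministic.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = schedule.span_s if t_end is None else float(t_end)
    times = np.arange(0.0, span + dt / 2.0, dt)
    irr = np.asarray(schedule.irradiance_at(times), float)

    g = params.g_H_plus
    tau = params.counterion_tau_s
    decay_p = math.exp(-g * dt) if g > 0 else 1.0
    decay_d = math.exp(-dt / tau) if tau > 0 else 0.0

    p = params.pmf_dark_mV
    d = params.dpsi_dark_mV
    n = times.size
    dpsi = np.empty(n)
    dpH = np.empty(n)
    pmf = np.empty(n)
    qe_series = np.empty(n)
    # scalar copies for the hot loop
    irr_list = irr.tolist()
    irr_half, influx_max = params.irr_half, params.influx_mV_per_s
    pmf_dark, dpsi_dark = params.pmf_dark_mV, params.dpsi_dark_mV
    dpH_dark = params.dpH_dark_mV
    frac, feedback = params.partition_fraction_dpsi, params.npq_feedback
    qe_max, hill, pK = params.qe_max, params.qe_hill, params.qe_pK
    stroma, mv_per_ph = params.stroma_pH, 59.1
    hill0 = 1.0 / (1.0 + 10.0 ** (hill * (stroma - dpH_dark / mv_per_ph - pK)))
    qe_scale = qe_max / (1.0 - hill0)
    for i in range(n):
        sat = irr_list[i] / (irr_list[i] + irr_half)
        x = max(p - d - dpH_dark, 0.0)  # light-driven dpH
        ph = stroma - (x + dpH_dark) / mv_per_ph
        hx = 1.0 / (1.0 + 10.0 ** (hill * (ph - pK)))
        qe_now = qe_scale * max(hx - hill0, 0.0)
        influx = influx_max * sat / (1.0 + feedback * qe_now)
        # exact relaxation of pmf toward its instantaneous steady state
        if g > 0:
            p_ss = pmf_dark + influx / g
            p_new = p_ss + (p - p_ss) * decay_p
        else:
            p_new = p + influx * dt
        delta = p_new - p
        # new pmf lands on dpsi first, then relaxes toward the partition target
        target = dpsi_dark + frac * (p_new - pmf_dark)
        d = target + (d + delta - target) * decay_d
        d = min(max(d, 0.0), p_new)
        p = p_new
        dpsi[i] = d
        pmf[i] = p
        dpH[i] = p - d
        qe_series[i] = qe_now

    out = pd.DataFrame({
        "time_s": times,
        "irradiance_umol": irr,
        "dpsi_mV": dpsi,
        "dpH_mV": dpH,
        "pmf_mV": pmf,
        "q_L": params.ql_from_irradiance(irr),
        "q_E": qe_series,
    })
    return out


# ---------------------------------------------------------------------------
# ECS traces
# ---------------------------------------------------------------------------

def _ecs_channels(times, signal_raw, irr, phase, noise: NoiseModel | None):
    """Wrap a raw ECS signal in three channels with removable backgrounds.

    The 520 nm channel carries the signal plus a shared drift; 505 and 535 nm
    carry the drift plus a component linear in wavelength, so that the
    (-1/2, 1, -1/2) deconvolution cancels both exactly.
    """
    drift = 5e-4 + 1e-7 * times          # shared slow baseline drift
    wl_slope = 1e-5                      # delta A per nm, linear background
    a505 = drift + wl_slope * (505 - 520)
    a520 = drift + signal_raw
    a535 = drift + wl_slope * (535 - 520)
    if noise is not None and noise.additive_sd > 0:
        rng = noise.rng()
        a505 = a505 + rng.normal(0.0, noise.additive_sd, times.size)
        a520 = a520 + rng.normal(0.0, noise.additive_sd, times.size)
        a535 = a535 + rng.normal(0.0, noise.additive_sd, times.size)
    return pd.DataFrame({
        "time_s": times, "a505": a505, "a520": a520, "a535": a535,
        "irradiance_umol": irr, "phase": phase,
    })


def synthesize_ecs_trace(pmf_series: pd.DataFrame, params: PlantParams,
                         dark_intervals, noise: NoiseModel | None = None) -> ECSTrace:
    """Emit a three-wavelength ECS trace for a simulated pmf time course.

    ``dark_intervals`` is a list of half-open ``(start_s, end_s)`` windows.
    Inside each window the 520 nm signal relaxes first-order at g_H+ from its
    light level and inverts below the dark baseline by an amount proportional
    to the light-driven dpH at light-off (the counter-ion recovery is slow on
    the <= 2 s scale of a dark interval and is not modeled inside it).
    """
    times = pmf_series["time_s"].to_numpy(float)
    dpsi = pmf_series["dpsi_mV"].to_numpy(float)
    dpH = pmf_series["dpH_mV"].to_numpy(float)
    irr = pmf_series["irradiance_umol"].to_numpy(float)

    intervals = sorted((float(a), float(b)) for a, b in dark_intervals)
    for (a, b) in intervals:
        if a >= b:
            raise ValueError("dark interval must have positive length")
        if a < times[0] or b > times[-1] + 1e-9:
            raise ValueError("dark interval outside the trace")
    for (_, b1), (a2, _) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise ValueError("overlapping dark intervals")

    k = params.ecs_per_mV
    sig_norm = k * (dpsi - params.dpsi_dark_mV)   # normalized units, light phases
    phase = np.full(times.size, "light", dtype=object)
    for (a, b) in intervals:
        mask = (times >= a) & (times < b)
        if not mask.any():
            continue
        i0 = np.argmax(mask)
        i_pre = max(i0 - 1, 0)
        s_off = sig_norm[i_pre]
        inv = k * max(dpH[i_pre] - params.dpH_dark_mV, 0.0)
        tt = times[mask] - times[i0]
        sig_norm[mask] = (s_off + inv) * np.exp(-params.g_H_plus * tt) - inv
        phase[mask] = "dark"
        irr = irr.copy()
        irr[mask] = 0.0

    raw = sig_norm * params.chl_per_area
    df = _ecs_channels(times, raw, irr, phase, noise)
    return ECSTrace(df, chl_per_area=params.chl_per_area)


def synthesize_ecs_from_amplitudes(ecs_ss: float, ecs_inv: float,
                                   g_H_plus: float = 20.0,
                                   chl_per_area: float = 20.0,
                                   dt: float = 0.002,
                                   baseline_dur: float = 5.0,
                                   light_dur: float = 10.0,
                                   dark_dur: float = 2.0,
                                   noise: NoiseModel | None = None) -> ECSTrace:
    """Construct a DIRK trace with known partition ground truth (trace units).

    Layout: pre-illumination dark baseline at 0, a light phase at ``ecs_ss``,
    then a dark interval decaying first-order at ``g_H_plus`` from ``ecs_ss``
    to ``-ecs_inv``.  Useful for exact round-trip tests of the partition and
    DIRK estimators.
    """
    t0 = np.arange(0.0, baseline_dur, dt)
    t1 = np.arange(baseline_dur, baseline_dur + light_dur, dt)
    t2 = np.arange(baseline_dur + light_dur,
                   baseline_dur + light_dur + dark_dur, dt)
    s0 = np.zeros_like(t0)
    s1 = np.full_like(t1, ecs_ss)
    s2 = (ecs_ss + ecs_inv) * np.exp(-g_H_plus * (t2 - t2[0])) - ecs_inv
    times = np.concatenate([t0, t1, t2])
    sig = np.concatenate([s0, s1, s2])
    phase = np.array(["dark"] * t0.size + ["light"] * t1.size + ["dark"] * t2.size,
                     dtype=object)
    irr = np.where(phase == "light", 500.0, 0.0)
    raw = sig * chl_per_area
    df = _ecs_channels(times, raw, irr, phase, noise)
    return ECSTrace(df, chl_per_area=chl_per_area)


# ---------------------------------------------------------------------------
# fluorescence traces
# ---------------------------------------------------------------------------

def fluorescence_levels(params: PlantParams, dpH_mV, q_L, damage=0.0):
    """Ground-truth fluorescence levels for a physiological state.

    Quenching acts multiplicatively on F_M (damage removes F_M at fixed F_0):
    F_M' = F_M / (1 + q_E + q_I) and F_M_rec = F_M / (1 + q_I), so the
    Stern-Volmer estimators recover q_E and q_I exactly.  F_S is back-solved
    from the target q_L given F_0'.
    """
    fm = params.fm_dark
    f0 = params.f0_dark
    qe = params.qe_from_dpH(dpH_mV)
    qi = params.qi_per_damage * np.asarray(damage, float)
    fmp = fm / (1.0 + qe + qi)
    fm_rec = fm / (1.0 + qi)
    f0p = f0 / (params.fvfm_dark + f0 / fmp)
    ql = np.asarray(q_L, float)
    fs = fmp * f0p / (f0p + ql * (fmp - f0p))
    return dict(F0=f0, FM=fm, FMp=fmp, FM_rec=fm_rec, F0p=f0p, FS=fs,
                qe=qe, qi=qi)


def synthesize_fluorescence_trace(pmf_series: pd.DataFrame, params: PlantParams,
                                  pulse_times, noise: NoiseModel | None = None,
                                  damage_series=None) -> FluorTrace:
    """Emit a pulse-annotated fluorescence trace for a pmf time course.

    ``pulse_times`` must be sorted and lie within the series.  At each pulse
    the trace jumps to the current F_M' for :data:`PULSE_DURATION_S`.
    ``damage_series`` (same length as the series) sets the damaged-PSII
    fraction driving q_I; default undamaged.  ``dark_start`` events are
    emitted at every light-to-dark transition of the series.
    """
    times = pmf_series["time_s"].to_numpy(float)
    dpH = pmf_series["dpH_mV"].to_numpy(float)
    ql = pmf_series["q_L"].to_numpy(float)
    irr = pmf_series["irradiance_umol"].to_numpy(float)
    dmg = np.zeros_like(times) if damage_series is None else np.asarray(damage_series, float)

    pulse_times = list(pulse_times)
    if pulse_times != sorted(pulse_times):
        raise ValueError("pulse_times must be sorted")
    if pulse_times and (pulse_times[0] < times[0] or pulse_times[-1] > times[-1]):
        raise ValueError("pulses must lie within the trace")

    # light-driven dpH only: quenching relaxes as the lumen re-equilibrates
    dpH_light = np.maximum(dpH - params.dpH_dark_mV, 0.0)
    lv = fluorescence_levels(params, dpH_light, ql, dmg)
    fs, fmp = np.asarray(lv["FS"], float), np.asarray(lv["FMp"], float)

    # during a saturation pulse the leaf sits at F_M'
    in_pulse = np.zeros(times.size, bool)
    pulse_level = np.full(times.size, np.nan)
    for tp in pulse_times:
        idx = int(np.searchsorted(times, tp, side="right") - 1)
        mask = (times >= tp) & (times <= tp + PULSE_DURATION_S)
        in_pulse |= mask
        pulse_level[mask] = fmp[idx]

    rows = []
    j = 0
    for i, t in enumerate(times):
        while j < len(pulse_times) and pulse_times[j] <= t:
            tp = pulse_times[j]
            idx = int(np.searchsorted(times, tp, side="right") - 1)
            rows.append((tp, float(fmp[idx]), "pulse_start"))
            rows.append((tp + PULSE_DURATION_S, float(fmp[idx]), "pulse_end"))
            j += 1
        event = "none"
        if i > 0 and irr[i] == 0.0 and irr[i - 1] > 0.0:
            event = "dark_start"
        level = pulse_level[i] if in_pulse[i] else fs[i]
        rows.append((t, float(level), event))
    df = pd.DataFrame(rows, columns=["time_s", "fluor", "event"])
    df = df.sort_values("time_s", kind="mergesort").reset_index(drop=True)
    if noise is not None and noise.additive_sd > 0:
        rng = noise.rng()
        df["fluor"] = df["fluor"] + rng.normal(0.0, noise.additive_sd, len(df))
    return FluorTrace(df)


# ---------------------------------------------------------------------------
# photoinhibition and flash assays
# ---------------------------------------------------------------------------

def simulate_photoinhibition(params: PlantParams, schedule: LightSchedule,
                             lincomycin: bool = False, seed: int | None = None,
                             dt: float = 1.0) -> pd.DataFrame:
    """Active-PSII fraction and normalized F_V/F_M over a light schedule.

    Damage per unit time is ``damage_coeff * v_r`` with the recombination
    rate v_r = k_r (1 - q_L) 10^(dpsi_light-dark / 60) evaluated along the pmf
    trajectory; repair is first-order unless blocked by lincomycin.  The
    normalized F_V/F_M is identified with the active-PSII fraction.
    """
    series = simulate_pmf_dynamics(params, schedule, dt=dt, seed=seed)
    dpsi_ld = np.maximum(series["dpsi_mV"].to_numpy() - params.dpsi_dark_mV, 0.0)
    ql = series["q_L"].to_numpy()
    v_r = params.k_r * (1.0 - ql) * 10.0 ** (dpsi_ld / 60.0)
    k_dmg = params.damage_coeff * v_r
    k_rep = 0.0 if lincomycin else params.repair_rate

    n = len(series)
    active = np.empty(n)
    a = params.psii_fraction_active
    for i in range(n):
        k_tot = k_dmg[i] + k_rep
        if k_tot > 0:
            a_ss = k_rep / k_tot
            a = a_ss + (a - a_ss) * math.exp(-k_tot * dt)
        active[i] = a
    return pd.DataFrame({
        "time_s": series["time_s"],
        "irradiance_umol": series["irradiance_umol"],
        "active_fraction": active,
        "fvfm_norm": active / params.psii_fraction_active,
        "v_r": v_r,
        "damage": 1.0 - active,
    })


@dataclass
class FlashPair:
    """ECS amplitudes after two consecutive single-turnover flashes.

    The first flash turns over PSI plus every still-active PSII; the second,
    fired before PSII recovers, turns over PSI only, so amp1 - amp2 isolates
    the active-PSII contribution.
    """

    amp1: float
    amp2: float

    @property
    def psii_activity(self) -> float:
        return self.amp1 - self.amp2


def simulate_flash_ecs(psii_fraction_active: float, psi_amplitude: float = 4e-4,
                       noise: NoiseModel | None = None,
                       psii_amplitude: float | None = None) -> FlashPair:
    """Flash-pair ECS amplitudes for a given active-PSII fraction."""
    if not 0.0 <= psii_fraction_active <= 1.0:
        raise ValueError("psii_fraction_active must lie in [0, 1]")
    if psii_amplitude is None:
        psii_amplitude = psi_amplitude
    amp1 = psi_amplitude + psii_fraction_active * psii_amplitude
    amp2 = psi_amplitude
    if noise is not None and noise.additive_sd > 0:
        rng = noise.rng()
        amp1 += rng.normal(0.0, noise.additive_sd)
        amp2 += rng.normal(0.0, noise.additive_sd)
    return FlashPair(float(amp1), float(amp2))
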