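"""Saturation-pulse (PAM) chlorophyll fluorescence parameters.

Dark-adapted leaves give the minimal and maximal fluorescence F0 and FM;
under actinic light a saturating pulse gives the momentary maximum FM' and
the pre-pulse steady state FS; after >= 10 min of dark relaxation the
recovered maximum FM_rec separates the rapidly reversible, lumen-pH-driven
quenching (q_E) from the slowly reversible photoinhibitory part (q_I):

    F_V/F_M   = (FM - F0) / FM          maximal PSII quantum efficiency
    Phi_II    = (FM' - FS) / FM'        operating efficiency
    LEF       = Phi_II * PAR * absorptance * PSII fraction
    q_E(SV)   = FM/FM' - FM/FM_rec      Stern-Volmer, q_I removed
    q_I       = FM/FM_rec - 1
    q_L       = (FM'-FS)/(FM'-F0') * F0'/FS   oxidized-Q_A estimate

All ratio parameters are invariant under rescaling of fluorescence units;
q_E(SV) + q_I equals the total Stern-Volmer NPQ, FM/FM' - 1, exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FluorTrace

__all__ = [
    "PulseRecord", "PAMQuantification", "fvfm", "phi2", "lef", "qe_qi_sv",
    "ql", "estimate_f0prime", "integrate_daily", "log2_fold_change",
    "compute_pam", "extract_pulses", "pam_table",
]


@dataclass
class PulseRecord:
    """Fluorescence levels for one light-phase saturation pulse."""

    F0: float
    FM: float
    FS: float
    FMp: float
    FM_rec: float
    F0p: float | None = None
    irradiance: float = np.nan
    recovery_min: float = np.nan   # dark relaxation behind FM_rec


@dataclass
class PAMQuantification:
    fvfm: float
    phi2: float
    lef: float
    qe_sv: float
    qi: float
    ql: float
    npq: float
    flags: tuple[str, ...] = ()


def fvfm(F0: float, FM: float) -> float:
    if F0 <= 0 or FM <= 0 or FM < F0:
        raise ValueError("need FM >= F0 > 0")
    return (FM - F0) / FM


def phi2(FS: float, FMp: float) -> float:
    if FS <= 0 or FMp <= 0 or FS > FMp:
        raise ValueError("need FMp >= FS > 0")
    return (FMp - FS) / FMp


def lef(phi2_value: float, par: float, absorptance: float = 0.84,
        psii_fraction: float = 0.5) -> float:
    """Linear electron flow, umol electrons m^-2 s^-1.

    The 0.84 leaf absorptance and 0.5 PSII excitation fraction are the
    community defaults for leaves; both are exposed.
    """
    if par < 0:
        raise ValueError("par must be >= 0")
    return phi2_value * par * absorptance * psii_fraction


def qe_qi_sv(FM: float, FMp: float, FM_rec: float) -> tuple[float, float]:
    """Stern-Volmer q_E and q_I from FM, FM' and the dark-recovered FM.

    Values can be negative on drifting real data; callers flag rather than
    clip them.
    """
    if min(FM, FMp, FM_rec) <= 0:
        raise ValueError("fluorescence levels must be positive")
    qe_sv = FM / FMp - FM / FM_rec
    qi = FM / FM_rec - 1.0
    return qe_sv, qi


def ql(FS: float, FMp: float, F0p: float) -> float:
    """Fraction of oxidized Q_A from the 'lake model' fluorescence estimate."""
    if FMp <= 0 or F0p <= 0 or FS <= 0:
        raise ValueError("fluorescence levels must be positive")
    if FMp == F0p:
        raise ValueError("degenerate FMp == F0p")
    return (FMp - FS) / (FMp - F0p) * (F0p / FS)


def estimate_f0prime(F0: float, fvfm_value: float, FMp: float) -> float:
    """Estimate F0' when not measured: F0 / (F_V/F_M + F0/FM')."""
    if F0 <= 0 or FMp <= 0:
        raise ValueError("inputs must be positive")
    denom = fvfm_value + F0 / FMp
    if denom == 0:
        raise ValueError("zero denominator")
    return F0 / denom


def integrate_daily(times_h, values) -> float:
    """Trapezoidal integral of a daily parameter course (hours * units)."""
    t = np.asarray(times_h, float)
    v = np.asarray(values, float)
    if t.size < 2:
        raise ValueError("need at least 2 points to integrate")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted")
    return float(np.trapezoid(v, t))


def log2_fold_change(mutant_value: float, wildtype_value: float) -> float:
    if mutant_value <= 0 or wildtype_value <= 0:
        raise ValueError("fold changes need positive values")
    return float(np.log2(mutant_value / wildtype_value))


def compute_pam(rec: PulseRecord, absorptance: float = 0.84,
                psii_fraction: float = 0.5,
                min_recovery_min: float = 10.0) -> PAMQuantification:
    """All quenching parameters for one pulse record, with QC flags."""
    flags: list[str] = []
    fv = fvfm(rec.F0, rec.FM)
    p2 = phi2(rec.FS, rec.FMp)
    par = rec.irradiance if np.isfinite(rec.irradiance) else 0.0
    flow = lef(p2, par, absorptance, psii_fraction)
    qe_sv, qi = qe_qi_sv(rec.FM, rec.FMp, rec.FM_rec)
    if qe_sv < 0:
        flags.append("negative_qe")
    if qi < 0:
        flags.append("negative_qi")
    if np.isfinite(rec.recovery_min) and rec.recovery_min < min_recovery_min:
        flags.append("short_dark_relaxation")
    f0p = rec.F0p if rec.F0p is not None else estimate_f0prime(rec.F0, fv, rec.FMp)
    if rec.F0p is None:
        flags.append("f0prime_estimated")
    return PAMQuantification(
        fvfm=fv, phi2=p2, lef=flow, qe_sv=qe_sv, qi=qi,
        ql=ql(rec.FS, rec.FMp, f0p), npq=rec.FM / rec.FMp - 1.0,
        flags=tuple(flags))


# ---------------------------------------------------------------------------
# trace parsing
# ---------------------------------------------------------------------------

def extract_pulses(trace: FluorTrace, irradiance_at=None,
                   recovery_min: float = 10.0) -> list[PulseRecord]:
    """Parse a pulse-annotated fluorescence trace into pulse records.

    Conventions of the trace dialect: the first pulse is dark-adapted and
    defines F0 (the pre-pulse level) and FM; pulses fired at least
    ``recovery_min`` minutes after a ``dark_start`` event are dark-recovery
    pulses whose maximum becomes FM_rec for all preceding light-phase pulses
    back to the previous recovery point.  F0' is left for estimation.
    ``irradiance_at`` (callable of time) attaches PAR to each pulse.
    """
    df = trace.data
    t = df["time_s"].to_numpy(float)
    f = df["fluor"].to_numpy(float)
    ev = df["event"].to_numpy(object)

    starts = np.flatnonzero(ev == "pulse_start")
    ends = np.flatnonzero(ev == "pulse_end")
    if starts.size == 0 or starts.size != ends.size:
        raise ValueError("trace has unmatched pulse markers")
    dark_starts = t[np.flatnonzero(ev == "dark_start")]

    pulses = []
    for i0, i1 in zip(starts, ends):
        tp = t[i0]
        plateau = f[i0:i1 + 1]
        fmp = float(np.mean(plateau))
        # steady state from the trailing pre-pulse samples (<= 10 s back)
        before = np.flatnonzero((ev[:i0] == "none") | (ev[:i0] == "dark_start"))
        if before.size:
            recent = before[t[before] >= tp - 10.0][-5:]
            if recent.size == 0:
                recent = before[-1:]
            fs = float(np.mean(f[recent]))
        else:
            fs = float(f[0])
        since_dark = tp - dark_starts[dark_starts <= tp]
        rec_min = float(since_dark.min() / 60.0) if since_dark.size else np.nan
        pulses.append(dict(t=tp, FMp=fmp, FS=fs, rec_min=rec_min))

    F0 = pulses[0]["FS"]
    FM = pulses[0]["FMp"]

    # assign FM_rec: for each light pulse, the next dark-recovery pulse
    rec_pulses = [p for p in pulses if np.isfinite(p["rec_min"]) and p["rec_min"] >= recovery_min]
    records: list[PulseRecord] = []
    for p in pulses[1:]:
        if p in rec_pulses:
            continue
        later = [r for r in rec_pulses if r["t"] > p["t"]]
        fm_rec = later[0]["FMp"] if later else FM
        rec_recovery = later[0]["rec_min"] if later else np.nan
        irr = float(irradiance_at(p["t"])) if irradiance_at is not None else np.nan
        records.append(PulseRecord(F0=F0, FM=FM, FS=p["FS"], FMp=p["FMp"],
                                   FM_rec=fm_rec, irradiance=irr,
                                   recovery_min=rec_recovery))
    return records


def pam_table(records: list[PulseRecord], absorptance: float = 0.84,
              psii_fraction: float = 0.5) -> pd.DataFrame:
    """Per-pulse TSV-ready table of all quantification fields."""
    rows = []
    for rec in records:
        q = compute_pam(rec, absorptance, psii_fraction)
        rows.append({
            "irradiance_umol": rec.irradiance, "fvfm": q.fvfm, "phi2": q.phi2,
            "lef": q.lef, "qe_sv": q.qe_sv, "qi": q.qi, "ql": q.ql,
            "npq": q.npq, "flags": ";".join(q.flags) or "-",
        })
    return pd.DataFrame(rows)
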