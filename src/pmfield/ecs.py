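"""Quantification of electrochromic-shift (ECS) traces.

The ECS is a carotenoid absorbance band shift near 520 nm that reports the
trans-thylakoid electric field linearly.  Brief dark intervals during
actinic illumination (DIRK: dark-interval relaxation kinetics) let three
quantities be read off the deconvoluted signal:

* the first-order decay time constant, whose inverse is the proton
  conductivity of the ATP synthase, g_H+;
* the total relaxation amplitude ECS_t, proportional to the light-induced
  pmf;
* its split into ECS_ss (steady-state level minus dark baseline, the dpsi
  part) and ECS_inv (the inversion below the dark baseline, the dpH part).

Amplitudes are normalized to leaf chlorophyll content (deconvoluted
delta-A520 per ug chlorophyll per cm^2) so genotypes with different pigment
levels are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import ECSTrace

__all__ = [
    "FitError", "DirkFit", "PmfPartition", "P700Fit", "DEFAULT_WEIGHTS",
    "deconvolute_ecs", "fit_dirk", "partition_pmf", "partition_from_levels",
    "normalize_to_chl", "psii_activity_from_flash_pair", "fit_p700_halftime",
    "analyze_dirk_trace",
]

DEFAULT_WEIGHTS = (-0.5, 1.0, -0.5)


class FitError(RuntimeError):
    """A relaxation fit failed (flat, non-decaying, or below the noise floor)."""


# ---------------------------------------------------------------------------
# deconvolution and normalization
# ---------------------------------------------------------------------------

def deconvolute_ecs(a505, a520, a535, weights=DEFAULT_WEIGHTS) -> np.ndarray:
    """Weighted three-wavelength combination isolating the ECS band shift.

    With the default weights (-1/2, 1, -1/2) any background that is linear in
    wavelength across 505-535 nm cancels exactly (the weights sum to zero and
    have zero first moment about 520 nm).
    """
    a505 = np.asarray(a505, float)
    a520 = np.asarray(a520, float)
    a535 = np.asarray(a535, float)
    if not (a505.shape == a520.shape == a535.shape):
        raise ValueError("channel length mismatch")
    w505, w520, w535 = weights
    return w505 * a505 + w520 * a520 + w535 * a535


def normalize_to_chl(value, chl_per_area: float):
    """Express a delta-A amplitude per unit chlorophyll (ug^-1 cm^2)."""
    if chl_per_area <= 0:
        raise ValueError("chl_per_area must be positive")
    return np.asarray(value, float) / chl_per_area if np.ndim(value) else value / chl_per_area


# ---------------------------------------------------------------------------
# first-order relaxation fitting
# ---------------------------------------------------------------------------

def _window_mask(time: np.ndarray, window) -> np.ndarray:
    a, b = window
    return (time >= a) & (time < b)


def _fit_first_order(t: np.ndarray, y: np.ndarray):
    """Fit y = A exp(-t/tau) + C; returns (A, tau, C, rmse).

    Log-linear initialization followed by nonlinear least squares.  Raises
    :class:`FitError` for flat or non-decaying windows or when the fitted
    amplitude is not resolved above the residual noise.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if t.size < 10:
        raise FitError("dark window has fewer than 10 samples")
    scale = max(abs(float(y.max())), abs(float(y.min())), 1e-300)
    if float(y.max() - y.min()) <= 1e-9 * scale:
        raise FitError("flat trace")
    ts = t - t[0]
    tail = max(3, t.size // 10)
    c0 = float(np.mean(y[-tail:]))
    a0 = float(y[0] - c0)
    if a0 == 0.0:
        raise FitError("zero-amplitude window")
    z = (y - c0) / a0
    mask = z > 0.05
    tau0 = ts[-1] / 3.0
    if mask.sum() >= 3:
        zs, tt = np.log(z[mask]), ts[mask]
        slope = np.polyfit(tt, zs, 1)[0]
        if slope < 0:
            tau0 = -1.0 / slope
    try:
        popt, _ = curve_fit(
            lambda x, A, tau, C: A * np.exp(-x / tau) + C,
            ts, y, p0=[a0, tau0, c0], maxfev=20000)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - scipy detail
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    A, tau, C = (float(v) for v in popt)
    resid = y - (A * np.exp(-ts / tau) + C)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    if tau <= 0 or A <= 0:
        raise FitError("window is not a decaying first-order relaxation")
    if A < 3.0 * rmse:
        raise FitError("decay amplitude below the noise floor")
    return A, tau, C, rmse


@dataclass
class DirkFit:
    """First-order DIRK decay: amplitude (ECS_t candidate), tau, g_H+ = 1/tau."""

    ecs_t: float
    tau: float
    g_H_plus: float
    baseline: float
    fit_rmse: float


def _signal_from(trace_or_arrays, weights):
    if isinstance(trace_or_arrays, ECSTrace):
        d = trace_or_arrays.data
        sig = deconvolute_ecs(d["a505"], d["a520"], d["a535"], weights)
        return trace_or_arrays.time, np.asarray(sig, float), trace_or_arrays.chl_per_area
    time, sig = trace_or_arrays
    return np.asarray(time, float), np.asarray(sig, float), None


def fit_dirk(trace, dark_window, weights=DEFAULT_WEIGHTS,
             chl_per_area: float | None = None) -> DirkFit:
    """Fit the dark-interval ECS relaxation to a first-order exponential.

    ``trace`` is an :class:`~pmfield.io.ECSTrace` (deconvoluted internally)
    or a ``(time, signal)`` pair.  The amplitude is normalized to chlorophyll
    when a content is available.
    """
    time, sig, chl = _signal_from(trace, weights)
    if chl_per_area is not None:
        chl = chl_per_area
    mask = _window_mask(time, dark_window)
    A, tau, C, rmse = _fit_first_order(time[mask], sig[mask])
    if chl is not None:
        A, C, rmse = A / chl, C / chl, rmse / chl
    return DirkFit(ecs_t=A, tau=tau, g_H_plus=1.0 / tau, baseline=C,
                   fit_rmse=rmse)


# ---------------------------------------------------------------------------
# pmf partitioning
# ---------------------------------------------------------------------------

@dataclass
class PmfPartition:
    """ECS_t = ECS_ss + ECS_inv decomposition of the light-induced pmf."""

    ecs_t: float
    ecs_ss: float
    ecs_inv: float
    fraction_dpsi: float
    flags: tuple[str, ...] = ()


def partition_from_levels(S: float, D: float, M: float) -> PmfPartition:
    """Partition arithmetic from the three signal levels.

    S = mean steady-state light level, D = dark baseline, M = dark-interval
    minimum: ECS_t = S - M, ECS_ss = S - D, ECS_inv = D - M.  A minimum above
    the baseline (no inversion) clamps ECS_inv to 0 with a warning flag.
    """
    flags: list[str] = []
    ecs_t = S - M
    ecs_ss = S - D
    ecs_inv = D - M
    if ecs_inv < 0:
        flags.append("no_inversion")
        ecs_inv = 0.0
    if ecs_t > 0:
        fraction = ecs_ss / ecs_t
    else:
        fraction = 0.0
        if ecs_t == 0:
            flags.append("zero_amplitude")
    return PmfPartition(ecs_t, ecs_ss, ecs_inv, fraction, tuple(flags))


def partition_pmf(trace, light_window, dark_window,
                  dark_baseline_window=None, weights=DEFAULT_WEIGHTS,
                  chl_per_area: float | None = None,
                  smooth: int = 5) -> PmfPartition:
    """Partition the light-induced pmf from a DIRK trace.

    The dark baseline D defaults to the mean over ``dark_baseline_window``
    (normally a pre-illumination dark segment).  Without one, the signal is
    taken as referenced to the dark-adapted baseline (D = 0) and flagged.
    The dark-interval minimum is taken from a lightly smoothed signal to
    reduce the noise bias of the min statistic.
    """
    time, sig, chl = _signal_from(trace, weights)
    if chl_per_area is not None:
        chl = chl_per_area
    lmask = _window_mask(time, light_window)
    dmask = _window_mask(time, dark_window)
    if not lmask.any() or not dmask.any():
        raise ValueError("light/dark windows select no samples")
    S = float(sig[lmask].mean())
    flags: list[str] = []
    if dark_baseline_window is not None:
        bmask = _window_mask(time, dark_baseline_window)
        if not bmask.any():
            raise ValueError("baseline window selects no samples")
        D = float(sig[bmask].mean())
    else:
        D = 0.0
        flags.append("baseline_assumed_zero")
    dark = sig[dmask]
    if smooth > 1 and dark.size >= smooth:
        kernel = np.ones(smooth) / smooth
        dark = np.convolve(dark, kernel, mode="valid")
    M = float(dark.min())
    part = partition_from_levels(S, D, M)
    if chl is not None:
        part = PmfPartition(part.ecs_t / chl, part.ecs_ss / chl,
                            part.ecs_inv / chl, part.fraction_dpsi,
                            part.flags)
    return PmfPartition(part.ecs_t, part.ecs_ss, part.ecs_inv,
                        part.fraction_dpsi, part.flags + tuple(flags))


# ---------------------------------------------------------------------------
# flash pairs and P700
# ---------------------------------------------------------------------------

def psii_activity_from_flash_pair(pair) -> tuple[float, tuple[str, ...]]:
    """Active-PSII signal: first-flash minus second-flash ECS amplitude.

    Negative results (second flash larger) are returned as-is with a flag so
    instrument drift surfaces rather than being clipped.
    """
    amp1, amp2 = float(pair.amp1), float(pair.amp2)
    if not (np.isfinite(amp1) and np.isfinite(amp2)):
        raise ValueError("flash amplitudes must be finite")
    activity = amp1 - amp2
    flags = ("negative_activity",) if activity < 0 else ()
    return activity, flags


@dataclass
class P700Fit:
    """First-order P700+ reduction: half_time = ln2 / rate."""

    half_time: float
    rate: float
    fit_rmse: float


def fit_p700_halftime(time, signal_810nm, dark_window) -> P700Fit:
    """Half-time of the first-order P700+ reduction during a dark interval."""
    time = np.asarray(time, float)
    sig = np.asarray(signal_810nm, float)
    mask = _window_mask(time, dark_window)
    A, tau, C, rmse = _fit_first_order(time[mask], sig[mask])
    return P700Fit(half_time=float(np.log(2.0) * tau), rate=1.0 / tau,
                   fit_rmse=rmse)


# ---------------------------------------------------------------------------
# per-measurement table
# ---------------------------------------------------------------------------

def analyze_dirk_trace(trace: ECSTrace, light_window, dark_window,
                       dark_baseline_window=None,
                       weights=DEFAULT_WEIGHTS) -> pd.DataFrame:
    """One-row results table (ECS_t/ss/inv, g_H+, tau, rmse, flags) for a trace."""
    fit = fit_dirk(trace, dark_window, weights=weights)
    part = partition_pmf(trace, light_window, dark_window,
                         dark_baseline_window, weights=weights)
    return pd.DataFrame([{
        "ecs_t": part.ecs_t, "ecs_ss": part.ecs_ss, "ecs_inv": part.ecs_inv,
        "fraction_dpsi": part.fraction_dpsi, "g_H_plus": fit.g_H_plus,
        "tau_s": fit.tau, "fit_rmse": fit.fit_rmse,
        "flags": ";".join(part.flags) or "-",
    }])
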