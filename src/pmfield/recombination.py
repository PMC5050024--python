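"""Field-dependent PSII charge recombination and the ECS -> mV calibration.

The S2QA- state recombines through the P+Pheo- pathway at a rate set by the
free energy stabilizing the charge-separated pair.  An electric field dpsi
across the membrane destabilizes P+QA- and shifts the QA-/Pheo sharing
equilibrium by one decade per 60 mV, so

    v_r = k_r * (1 - q_L) * 10^(dpsi_light-dark / 60 mV)

with k_r the intrinsic rate at zero field with fully reduced Q_A (0.3 s^-1)
and 1 - q_L the reduced-Q_A fraction.  Written in energy terms this is
v_r = [S2QA-] * k_r' * 10^(-dE_stab / 0.06 eV) with dE_stab lowered by
dpsi/1000 eV.  The "physical" sign convention (field accelerates
recombination) is the default; the "as_printed" option negates the exponent.

The calibration chain converts normalized ECS amplitudes to mV using the
single-turnover-flash field (~40 mV per flash) and the dark pmf
(~112 mV, about half stored as dpsi).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "Calibration", "RecombinationModel", "RecombinationEstimate",
    "calibrate_ecs_to_mv", "recombination_rate", "stabilization_rate_factor",
    "predicted_fold_change", "steady_state_dpsi_range",
    "transient_dpsi_bounds", "qi_association", "AssociationReport",
]


@dataclass
class Calibration:
    """ECS -> mV conversion constants from the flash calibration."""

    mv_per_flash: float = 40.0          # field from one saturating single-turnover flash
    pmf_dark_mV: float = 112.0          # dark pmf from equilibration with ATP
    dark_fraction_dpsi: float = 0.5
    flash_ecs_amplitude: float = 4e-4   # normalized ECS units per flash

    def __post_init__(self) -> None:
        for name in ("mv_per_flash", "pmf_dark_mV", "dark_fraction_dpsi",
                     "flash_ecs_amplitude"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def dark_dpsi_mV(self) -> float:
        """The printed dark dpsi (60 mV); see also the exact product."""
        return 60.0

    @property
    def dark_dpsi_exact_mV(self) -> float:
        return self.pmf_dark_mV * self.dark_fraction_dpsi


@dataclass
class RecombinationModel:
    k_r: float = 0.3                    # s^-1, zero-field rate at q_L = 0
    decade_mV: float = 60.0             # mV per 10-fold rate change
    decade_eV: float = 0.06             # eV per 10-fold (same constant)
    sign_convention: str = "physical"   # or "as_printed"

    def __post_init__(self) -> None:
        if abs(self.decade_eV * 1000.0 - self.decade_mV) > 1e-9:
            raise ValueError("decade_eV * 1000 must equal decade_mV")
        if self.sign_convention not in ("physical", "as_printed"):
            raise ValueError("sign_convention must be physical or as_printed")
        if self.k_r < 0 or self.decade_mV <= 0:
            raise ValueError("rates must be non-negative, decade positive")


@dataclass
class RecombinationEstimate:
    v_r: float
    q_L: float
    dpsi_mV: float
    sign_convention: str


def calibrate_ecs_to_mv(ecs_value: float, cal: Calibration) -> float:
    """Convert a normalized ECS amplitude to mV via the flash calibration."""
    if cal.flash_ecs_amplitude <= 0:
        raise ValueError("flash amplitude missing")
    return ecs_value * cal.mv_per_flash / cal.flash_ecs_amplitude


def stabilization_rate_factor(delta_e_stab_eV: float,
                              decade_eV: float = 0.06) -> float:
    """Rate factor 10^(-dE_stab / decade) of the energy-gap form."""
    return 10.0 ** (-delta_e_stab_eV / decade_eV)


def recombination_rate(q_L: float, dpsi_mV: float,
                       model: RecombinationModel | None = None,
                       dielectric_weight: float = 1.0) -> RecombinationEstimate:
    """S2QA- recombination rate at a Q_A redox poise and light-dark field.

    ``dielectric_weight`` scales the fraction of the field acting on the
    Pheo -> Q_A span (default 1: the full field, as applied in vivo).
    """
    model = model or RecombinationModel()
    if not 0.0 <= q_L <= 1.0:
        raise ValueError("q_L must lie in [0, 1]")
    sign = 1.0 if model.sign_convention == "physical" else -1.0
    factor = 10.0 ** (sign * dielectric_weight * dpsi_mV / model.decade_mV)
    v_r = model.k_r * (1.0 - q_L) * factor
    return RecombinationEstimate(v_r=v_r, q_L=q_L, dpsi_mV=dpsi_mV,
                                 sign_convention=model.sign_convention)


def predicted_fold_change(dpsi_mV: float,
                          model: RecombinationModel | None = None) -> float:
    """Boltzmann fold-change of the recombination rate for a field step."""
    model = model or RecombinationModel()
    return 10.0 ** (dpsi_mV / model.decade_mV)


def steady_state_dpsi_range(pmf_low: float = 150.0, pmf_high: float = 200.0,
                            frac_low: float = 0.20, frac_high: float = 0.60
                            ) -> tuple[float, float]:
    """Range of steady-state light-driven dpsi from pmf and partition bounds."""
    if pmf_low > pmf_high or frac_low > frac_high:
        raise ValueError("bounds inverted")
    if not (0.0 <= frac_low <= 1.0 and 0.0 <= frac_high <= 1.0):
        raise ValueError("fractions must lie in [0, 1]")
    return pmf_low * frac_low, pmf_high * frac_high


def transient_dpsi_bounds(dark_dpsi: float = 60.0,
                          steady_range: tuple[float, float] = (30.0, 120.0),
                          spike_range: tuple[float, float] = (60.0, 80.0)
                          ) -> tuple[float, float]:
    """Total dpsi bounds during light fluctuations: dark + steady + spike."""
    if dark_dpsi < 0 or min(steady_range) < 0 or min(spike_range) < 0:
        raise ValueError("inputs must be non-negative")
    return (dark_dpsi + steady_range[0] + spike_range[0],
            dark_dpsi + steady_range[1] + spike_range[1])


# ---------------------------------------------------------------------------
# q_I association statistics
# ---------------------------------------------------------------------------

@dataclass
class AssociationReport:
    """Two-way ANOVA of q_I against the dpsi (ECS_ss) and dpH (ECS_inv) axes."""

    f_ecs_ss: float
    p_ecs_ss: float
    f_ecs_inv: float
    p_ecs_inv: float
    nobs: int
    df_resid: int

    def __str__(self) -> str:  # text report for the CLI
        return (
            "Two-way ANOVA of q_I on pmf components (Type II SS)\n"
            f"  n = {self.nobs}, residual df = {self.df_resid}\n"
            f"  ECS_ss  (dpsi): F = {self.f_ecs_ss:.3g}, p = {self.p_ecs_ss:.3g}\n"
            f"  ECS_inv (dpH):  F = {self.f_ecs_inv:.3g}, p = {self.p_ecs_inv:.3g}\n"
        )


def qi_association(table: pd.DataFrame, response: str = "qi",
                   predictors: tuple[str, str] = ("ecs_ss", "ecs_inv")
                   ) -> AssociationReport:
    """Type II two-way ANOVA of per-plant q_I on the two pmf components.

    ``table`` needs one row per plant with the response and both predictor
    columns.  Constant or (near-)collinear predictors are rejected.
    """
    cols = [response, *predictors]
    df = table[cols].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete rows")
    x1, x2 = (df[p].to_numpy(float) for p in predictors)
    if np.std(x1) == 0 or np.std(x2) == 0:
        raise ValueError("constant predictor")
    r = np.corrcoef(x1, x2)[0, 1]
    if not np.isfinite(r) or abs(r) > 1.0 - 1e-9:
        raise ValueError("collinear predictors")
    work = df.rename(columns={response: "y", predictors[0]: "x1",
                              predictors[1]: "x2"})
    fit = ols("y ~ x1 + x2", data=work).fit()
    table2 = anova_lm(fit, typ=2)
    return AssociationReport(
        f_ecs_ss=float(table2.loc["x1", "F"]),
        p_ecs_ss=float(table2.loc["x1", "PR(>F)"]),
        f_ecs_inv=float(table2.loc["x2", "F"]),
        p_ecs_inv=float(table2.loc["x2", "PR(>F)"]),
        nobs=int(fit.nobs), df_resid=int(fit.df_resid))
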