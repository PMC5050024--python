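"""Physiological parameter sets for the synthetic plant model.

A :class:`PlantParams` instance describes one genotype: how fast its ATP
synthase lets protons out of the thylakoid lumen (``g_H_plus``), how the
steady-state proton motive force (pmf) is split between the electric field
(dpsi) and the pH gradient, how energy-dependent quenching (q_E) responds to
lumen acidification, and how susceptible photosystem II is to
recombination-driven photodamage.  All downstream synthetic traces are
deterministic functions of one of these parameter sets plus a light schedule
and a :class:`NoiseModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PlantParams", "NoiseModel", "load_params", "dump_params"]

# mV of electrochemical potential per pH unit at room temperature
MV_PER_PH_UNIT = 59.1


@dataclass
class PlantParams:
    """Per-genotype physiology.

    Rates are s^-1, potentials mV, irradiances umol photons m^-2 s^-1,
    chlorophyll ug cm^-2.  Defaults describe a healthy wild-type Arabidopsis
    rosette; mutants with impaired ATP synthase are modeled by scaling
    ``g_H_plus`` down.
    """

    # proton circuit
    g_H_plus: float = 20.0             # proton conductivity (inverse ECS decay time)
    partition_fraction_dpsi: float = 0.5  # steady-state share of light-driven pmf in dpsi
    dark_fraction_dpsi: float = 0.5    # share of the dark (ATP-equilibrated) pmf in dpsi
    pmf_dark_mV: float = 112.0         # dark pmf set by equilibration with the ATP pool
    influx_mV_per_s: float = 3200.0    # light-saturated proton influx, pmf-units per second
    irr_half: float = 300.0            # half-saturation irradiance of electron flow
    counterion_tau_s: float = 20.0     # counter-ion relaxation converting dpsi into dpH
    npq_feedback: float = 1.0          # strength of q_E feedback throttling proton influx

    # leaf optics / pigments
    chl_per_area: float = 20.0         # ug chlorophyll cm^-2

    # PSII recombination and photoinhibition
    k_r: float = 0.3                   # intrinsic S2QA- recombination rate, zero field
    damage_coeff: float = 1e-4         # PSII inactivations per recombination event
    repair_rate: float = 2e-4          # first-order D1 repair rate, s^-1
    psii_fraction_active: float = 1.0

    # q_E response to lumen pH (Hill function)
    qe_pK: float = 6.0
    qe_hill: float = 2.0
    qe_max: float = 3.5                # saturating q_E amplitude
    stroma_pH: float = 7.8

    # Q_A redox poise vs irradiance (saturating)
    ql_min: float = 0.1
    ql_irr_half: float = 300.0

    # fluorescence scale
    fm_dark: float = 4000.0            # dark-adapted F_M in instrument units
    fvfm_dark: float = 0.75            # dark-adapted F_V/F_M of undamaged leaves
    qi_per_damage: float = 2.0         # Stern-Volmer q_I per unit damaged-PSII fraction

    # ECS optics: normalized ECS units (delta A per ug chl cm^-2) per mV of dpsi
    ecs_per_mV: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("g_H_plus", "pmf_dark_mV", "influx_mV_per_s", "irr_half",
                     "counterion_tau_s", "chl_per_area", "k_r", "damage_coeff",
                     "repair_rate", "qe_max", "qi_per_damage", "ecs_per_mV",
                     "fm_dark", "npq_feedback"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("partition_fraction_dpsi", "dark_fraction_dpsi",
                     "psii_fraction_active", "ql_min", "fvfm_dark"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    # -- derived dark-state quantities -------------------------------------
    @property
    def dpsi_dark_mV(self) -> float:
        return self.dark_fraction_dpsi * self.pmf_dark_mV

    @property
    def dpH_dark_mV(self) -> float:
        return self.pmf_dark_mV - self.dpsi_dark_mV

    @property
    def f0_dark(self) -> float:
        return self.fm_dark * (1.0 - self.fvfm_dark)

    # -- response curves ----------------------------------------------------
    def lumen_pH(self, dpH_light_mV):
        """Lumen pH for a light-driven dpH (mV) on top of the dark gradient."""
        total = np.asarray(dpH_light_mV, float) + self.dpH_dark_mV
        return self.stroma_pH - total / MV_PER_PH_UNIT

    def qe_from_dpH(self, dpH_light_mV):
        """Hill response of q_E to light-driven lumen acidification.

        The raw Hill curve in lumen pH is re-zeroed at the dark-adapted lumen
        pH so a dark leaf has exactly zero q_E, and rescaled to saturate at
        ``qe_max``.
        """
        h, pk = self.qe_hill, self.qe_pK
        hill = 1.0 / (1.0 + 10.0 ** (h * (self.lumen_pH(dpH_light_mV) - pk)))
        hill0 = 1.0 / (1.0 + 10.0 ** (h * (self.lumen_pH(0.0) - pk)))
        return self.qe_max * np.maximum(hill - hill0, 0.0) / (1.0 - hill0)

    def ql_from_irradiance(self, irradiance):
        """Saturating estimate of the oxidized Q_A fraction at an irradiance."""
        irr = np.asarray(irradiance, float)
        return self.ql_min + (1.0 - self.ql_min) / (1.0 + irr / self.ql_irr_half)

    def replace(self, **kwargs) -> "PlantParams":
        d = asdict(self)
        d.update(kwargs)
        return PlantParams(**d)


@dataclass
class NoiseModel:
    """Additive Gaussian measurement noise; one seed drives a whole run."""

    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0:
            raise ValueError("additive_sd must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def load_params(path: str | Path) -> PlantParams:
    """Read a PlantParams key-value config (YAML); unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PlantParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown PlantParams keys: {sorted(unknown)}")
    return PlantParams(**raw)


def dump_params(params: PlantParams, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(params), sort_keys=True))
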