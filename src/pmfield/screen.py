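"""End-to-end genotype screen: simulate, quantify, compare to wild type.

``run_screen`` plays the role of a three-day phenotyping experiment over a
panel of genotypes with different ATP synthase proton conductivities: each
genotype is simulated under each daily light schedule, PAM parameters are
read off the simulated physiology at the end of every light condition,
ECS/DIRK quantities come from full synthetic-trace fitting
(:func:`characterize_genotype`), and the results are summarized as
log2-fold changes vs the wild type, daily q_E/q_I integrals, per-genotype
photoinhibition rate constants, and the q_I ~ dpsi/dpH association ANOVA.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import curve_fit
from statsmodels.stats.multitest import multipletests

from .ecs import FitError, fit_dirk, partition_pmf
from .io import write_results_tsv
from .pam import integrate_daily, lef, log2_fold_change
from .params import NoiseModel, PlantParams
from .recombination import (AssociationReport, Calibration, RecombinationModel,
                            qi_association, recombination_rate)
from .schedules import LightSchedule, make_light_schedule
from .synth import (fluorescence_levels, simulate_photoinhibition,
                    simulate_pmf_dynamics, synthesize_ecs_trace)

__all__ = ["ScreenConfig", "ScreenResult", "run_screen", "sort_by_ghplus",
           "fit_photoinhibition_course", "characterize_genotype",
           "default_screen_config"]


@dataclass
class ScreenConfig:
    genotypes: dict[str, PlantParams]
    wild_type: str
    schedules: dict[str, LightSchedule]
    seed: int = 0
    n_replicates: int = 3
    replicate_sd: float = 0.05        # relative measurement scatter per replicate
    sim_dt_s: float = 2.0
    reference_irradiance: float = 500.0
    photoinhibition_irradiance: float = 1000.0
    photoinhibition_hours: float = 3.0
    calibration: Calibration = field(default_factory=Calibration)
    model: RecombinationModel = field(default_factory=RecombinationModel)

    def __post_init__(self) -> None:
        if self.wild_type not in self.genotypes:
            raise ValueError(f"wild type {self.wild_type!r} not among genotypes")
        if len(self.genotypes) < 2:
            raise ValueError("need the wild type plus at least one genotype")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def config_hash(self) -> str:
        blob = repr({
            "genotypes": {k: asdict(v) for k, v in sorted(self.genotypes.items())},
            "wild_type": self.wild_type,
            "schedules": {k: (s.steps, s.photoperiod_h, s.day_type)
                          for k, s in sorted(self.schedules.items())},
            "seed": self.seed, "n_replicates": self.n_replicates,
            "replicate_sd": self.replicate_sd, "sim_dt_s": self.sim_dt_s,
        }).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ScreenResult:
    measurements: pd.DataFrame             # deterministic per-timepoint table
    replicate_measurements: pd.DataFrame   # with per-replicate scatter
    fold_changes: pd.DataFrame
    daily_integrals: pd.DataFrame
    genotype_summary: pd.DataFrame
    stats: pd.DataFrame
    association: AssociationReport
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        """One TSV per table; the timepoint table is split per photoperiod."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        derived = [c for c in ("pmf_mV", "ecs_t") if c in self.measurements]
        for day, grp in self.measurements.groupby("day"):
            write_results_tsv(grp.drop(columns=derived),
                              out / f"measurements_{day}.tsv",
                              self.provenance, float_format="%.5g")
        for name in ("fold_changes", "daily_integrals", "genotype_summary",
                     "stats"):
            write_results_tsv(getattr(self, name), out / f"{name}.tsv",
                              self.provenance)
        (out / "association.txt").write_text(str(self.association))


# ---------------------------------------------------------------------------
# genotype characterization through the full trace pipeline
# ---------------------------------------------------------------------------

def characterize_genotype(params: PlantParams, irradiance: float = 500.0,
                          noise: NoiseModel | None = None,
                          dt: float = 0.01) -> dict:
    """Measure g_H+ and the pmf partition of one genotype by DIRK.

    Synthesizes a dark -> light -> dark-interval ECS trace for the genotype,
    then recovers everything through deconvolution, first-order DIRK fitting
    and partition arithmetic -- the same path a spectrometer trace would
    take.  Returns a dict of measured quantities in normalized ECS units.
    """
    schedule = LightSchedule(((0.0, 0.0), (20.0, float(irradiance))),
                             photoperiod_h=200.0 / 3600.0, day_type="constant")
    series = simulate_pmf_dynamics(params, schedule, dt=dt, t_end=203.0)
    trace = synthesize_ecs_trace(series, params, [(200.0, 202.5)], noise=noise)
    fit = fit_dirk(trace, dark_window=(200.0, 202.5))
    part = partition_pmf(trace, light_window=(150.0, 200.0),
                         dark_window=(200.0, 202.5),
                         dark_baseline_window=(5.0, 20.0))
    return {
        "g_H_plus": fit.g_H_plus, "tau_s": fit.tau,
        "ecs_t": part.ecs_t, "ecs_ss": part.ecs_ss, "ecs_inv": part.ecs_inv,
        "fraction_dpsi": part.fraction_dpsi, "fit_rmse": fit.fit_rmse,
        "flags": part.flags,
    }


# ---------------------------------------------------------------------------
# photoinhibition time-course fitting
# ---------------------------------------------------------------------------

def fit_photoinhibition_course(times, fvfm_series, normalize: bool = True):
    """Fit y(t) = y_inf + (1 - y_inf) exp(-k t) to an F_V/F_M time course.

    ``times`` may be in any unit; ``k`` comes back in its inverse.  Returns
    ``(k, report)`` where the report carries the plateau and residuals.
    Raises :class:`~pmfield.ecs.FitError` for flat or non-decaying series.
    """
    t = np.asarray(times, float)
    y = np.asarray(fvfm_series, float)
    if t.size < 4:
        raise FitError("need at least 4 time points")
    if normalize:
        y = y / y[0]
    decline = float(y[0] - y.min())
    if decline <= 1e-9 or y[-1] >= y[0]:
        raise FitError("series does not decay")
    y_inf0 = max(float(y.min()) - 0.01, 0.0)
    k0 = 1.0 / max(t[-1] - t[0], 1e-12)
    z = (y - y_inf0) / max(1.0 - y_inf0, 1e-12)
    mask = z > 0.05
    if mask.sum() >= 3:
        slope = np.polyfit(t[mask], np.log(z[mask]), 1)[0]
        if slope < 0:
            k0 = -slope
    try:
        popt, _ = curve_fit(
            lambda tt, k, y_inf: y_inf + (1.0 - y_inf) * np.exp(-k * tt),
            t, y, p0=[k0, y_inf0], bounds=([0.0, 0.0], [np.inf, 1.0]),
            maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"photoinhibition fit failed: {exc}") from exc
    k, y_inf = float(popt[0]), float(popt[1])
    resid = y - (y_inf + (1.0 - y_inf) * np.exp(-k * t))
    return k, {"y_inf": y_inf, "rmse": float(np.sqrt(np.mean(resid ** 2)))}


# ---------------------------------------------------------------------------
# the screen itself
# ---------------------------------------------------------------------------

def _measurement_times(schedule: LightSchedule) -> np.ndarray:
    """End of each light condition; hourly for a single-step (constant) day."""
    if len(schedule.steps) == 1:
        return np.arange(3600.0, schedule.span_s + 1.0, 3600.0)
    starts = [s for s, _ in schedule.steps[1:]] + [schedule.span_s]
    return np.asarray(starts, float)


def _timepoint_rows(name: str, day: str, params: PlantParams,
                    schedule: LightSchedule, dt: float,
                    model: RecombinationModel) -> list[dict]:
    series = simulate_pmf_dynamics(params, schedule, dt=dt)
    damage = simulate_photoinhibition(params, schedule, dt=dt)["damage"].to_numpy()
    t = series["time_s"].to_numpy()
    rows = []
    for tm in _measurement_times(schedule):
        # last sample strictly before the transition: end of the condition
        i = int(np.clip(np.searchsorted(t, tm, side="left") - 1, 0, t.size - 1))
        dpsi, dpH = series["dpsi_mV"].iat[i], series["dpH_mV"].iat[i]
        irr = series["irradiance_umol"].iat[i]
        ql_val = series["q_L"].iat[i]
        dpH_light = max(dpH - params.dpH_dark_mV, 0.0)
        lv = fluorescence_levels(params, dpH_light, ql_val, damage[i])
        phi2_val = (lv["FMp"] - lv["FS"]) / lv["FMp"]
        dpsi_light = max(dpsi - params.dpsi_dark_mV, 0.0)
        rows.append({
            "genotype": name, "day": day, "time_h": tm / 3600.0,
            "irradiance_umol": irr, "dpsi_mV": dpsi, "dpH_mV": dpH,
            "pmf_mV": series["pmf_mV"].iat[i], "q_L": ql_val,
            "q_E": float(lv["qe"]), "q_I": float(lv["qi"]),
            "phi2": phi2_val, "lef": lef(phi2_val, irr),
            "ecs_ss": params.ecs_per_mV * dpsi_light,
            "ecs_inv": params.ecs_per_mV * dpH_light,
            "ecs_t": params.ecs_per_mV * (dpsi_light + dpH_light),
            "v_r": recombination_rate(ql_val, dpsi_light, model).v_r,
        })
    return rows


def run_screen(config: ScreenConfig) -> ScreenResult:
    """Run the full synthetic screen; deterministic for a given config/seed."""
    rng = np.random.default_rng(config.seed)
    model = config.model

    # per-timepoint physiology for every genotype and day
    names = sorted(config.genotypes)
    rows: list[dict] = []
    for name in names:
        for day in sorted(config.schedules):
            rows.extend(_timepoint_rows(name, day, config.genotypes[name],
                                        config.schedules[day],
                                        config.sim_dt_s, model))
    meas = pd.DataFrame(rows)

    # replicates: multiplicative measurement scatter on the reported values
    value_cols = ["q_E", "q_I", "lef", "phi2", "ecs_ss", "ecs_inv", "ecs_t"]
    reps = []
    for r in range(config.n_replicates):
        rep = meas.copy()
        rep["replicate"] = r
        if config.replicate_sd > 0:
            scale = 1.0 + rng.normal(0.0, config.replicate_sd,
                                     (len(meas), len(value_cols)))
            rep[value_cols] = rep[value_cols].to_numpy() * scale
        reps.append(rep)
    replicates = pd.concat(reps, ignore_index=True)

    # log2-fold changes of the deterministic phenotype vs wild type
    mean_tbl = meas[["genotype", "day", "time_h", *value_cols]]
    wt_tbl = mean_tbl[mean_tbl["genotype"] == config.wild_type].set_index(
        ["day", "time_h"])
    fc_rows = []
    eps = 1e-9
    for _, row in mean_tbl.iterrows():
        wt = wt_tbl.loc[(row["day"], row["time_h"])]
        fc = {"genotype": row["genotype"], "day": row["day"],
              "time_h": row["time_h"]}
        for col in ("lef", "q_E", "q_I"):
            fc[f"log2_fc_{col}"] = log2_fold_change(max(row[col], eps),
                                                    max(wt[col], eps))
        fc_rows.append(fc)
    fold_changes = pd.DataFrame(fc_rows)

    # daily q_E / q_I integrals per replicate
    integ_rows = []
    for (name, day, r), grp in replicates.groupby(["genotype", "day", "replicate"]):
        grp = grp.sort_values("time_h")
        integ_rows.append({
            "genotype": name, "day": day, "replicate": r,
            "qe_integral": integrate_daily(grp["time_h"], grp["q_E"]),
            "qi_integral": integrate_daily(grp["time_h"], grp["q_I"]),
        })
    daily = pd.DataFrame(integ_rows)

    # Welch t-tests of daily integrals vs wild type, with a BH column
    stat_rows = []
    wt_name = config.wild_type
    for param in ("qe_integral", "qi_integral"):
        for day in sorted(config.schedules):
            wt_vals = daily.query("genotype == @wt_name and day == @day")[param]
            for name in names:
                if name == wt_name:
                    continue
                vals = daily.query("genotype == @name and day == @day")[param]
                t_stat, p = sps.ttest_ind(vals, wt_vals, equal_var=False)
                stat_rows.append({"genotype": name, "day": day,
                                  "parameter": param, "welch_t": float(t_stat),
                                  "p_value": float(p)})
    stats_tbl = pd.DataFrame(stat_rows)
    if len(stats_tbl):
        stats_tbl["p_bh"] = multipletests(stats_tbl["p_value"], method="fdr_bh")[1]

    # genotype summary through the DIRK pipeline, sorted by ascending g_H+
    summ_rows = []
    for name in names:
        p = config.genotypes[name]
        ch = characterize_genotype(p, irradiance=config.reference_irradiance)
        course = simulate_photoinhibition(
            p, make_light_schedule("constant", config.photoinhibition_hours,
                                   config.photoinhibition_irradiance),
            lincomycin=True, dt=2.0)
        sample = course.iloc[::300]  # every 10 min at dt = 2 s
        k_phot, rep = fit_photoinhibition_course(
            sample["time_s"] / 3600.0, sample["fvfm_norm"])
        summ_rows.append({
            "genotype": name, "is_wild_type": name == config.wild_type,
            "g_H_plus": ch["g_H_plus"], "ecs_t": ch["ecs_t"],
            "ecs_ss": ch["ecs_ss"], "ecs_inv": ch["ecs_inv"],
            "fraction_dpsi": ch["fraction_dpsi"],
            "k_photoinhibition_h": k_phot, "fvfm_plateau": rep["y_inf"],
        })
    summary = sort_by_ghplus(pd.DataFrame(summ_rows))

    # q_I ~ (ECS_ss, ECS_inv) association across genotype x replicate rows
    assoc_rows = []
    day_hi = sorted(config.schedules)[-1]
    for name in names:
        base = summary.set_index("genotype").loc[name]
        qi_reps = daily.query("genotype == @name and day == @day_hi")
        for _, r in qi_reps.iterrows():
            jitter = 1.0 + rng.normal(0.0, config.replicate_sd, 2)
            assoc_rows.append({
                "genotype": name, "qi": r["qi_integral"],
                "ecs_ss": base["ecs_ss"] * jitter[0],
                "ecs_inv": base["ecs_inv"] * jitter[1],
            })
    association = qi_association(pd.DataFrame(assoc_rows))

    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "n_replicates": config.n_replicates}
    return ScreenResult(measurements=meas, replicate_measurements=replicates,
                        fold_changes=fold_changes, daily_integrals=daily,
                        genotype_summary=summary, stats=stats_tbl,
                        association=association, provenance=provenance)


def sort_by_ghplus(table: pd.DataFrame) -> pd.DataFrame:
    """Stable ascending sort by measured g_H+, ties broken by genotype name."""
    for col in ("g_H_plus", "genotype"):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if table["g_H_plus"].isna().any():
        raise ValueError("missing g_H+ values")
    return (table.sort_values(["g_H_plus", "genotype"], kind="mergesort")
            .reset_index(drop=True))


def default_screen_config(seed: int = 0, n_replicates: int = 3) -> ScreenConfig:
    """A compact wild type + four ATP synthase mutants demonstration panel."""
    wt = PlantParams()
    genotypes = {
        "wildtype": wt,
        "gh30": wt.replace(g_H_plus=6.0, partition_fraction_dpsi=0.58,
                           chl_per_area=18.0),
        "gh40": wt.replace(g_H_plus=8.0, partition_fraction_dpsi=0.56,
                           chl_per_area=19.0),
        "gh60": wt.replace(g_H_plus=12.0, partition_fraction_dpsi=0.54,
                           chl_per_area=21.0),
        "gh120": wt.replace(g_H_plus=24.0, partition_fraction_dpsi=0.48,
                            chl_per_area=22.0),
    }
    schedules = {
        "day1_constant": make_light_schedule("constant", 16.0, 100.0),
        "day2_sinusoidal": make_light_schedule("sinusoidal", 16.0, 39.0, 500.0),
        "day3_fluctuating": make_light_schedule("fluctuating", 16.0, 39.0, 500.0),
    }
    return ScreenConfig(genotypes=genotypes, wild_type="wildtype",
                        schedules=schedules, seed=seed,
                        n_replicates=n_replicates)
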