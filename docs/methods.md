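# Methods

This note documents the models behind `pmfield`: what each stage assumes,
which parameters matter, what the synthetic data do and do not emulate, and
the numerical choices that were genuinely open.

## The proton circuit model

The generator treats the thylakoid as a single pool with a proton motive
force `pmf` (mV) obeying

    d(pmf)/dt = v_in(I, q_E) + g_H+ · pmf_dark − g_H+ · pmf

where `g_H+` (s⁻¹) is the ATP synthase proton conductivity, operationally
the inverse of the dark-interval ECS decay time constant. The term
`g_H+ · pmf_dark` represents equilibration with the stromal ATP pool: in
prolonged darkness the pmf relaxes to `pmf_dark` (112 mV by default, about
half of it stored as Δψ) rather than to zero, and this dark set point is
independent of `g_H+`. Light-driven proton influx saturates with irradiance
I and is throttled by the quenching feedback,

    v_in = v_max · I/(I + I_half) / (1 + q_E),

with `v_max` = 3200 mV s⁻¹ and `I_half` = 300 µmol m⁻² s⁻¹ chosen so that a
wild-type leaf (g_H+ = 20 s⁻¹) reaches a light-driven pmf of roughly
60–160 mV between 100 and 1000 µmol m⁻² s⁻¹ — the window consistent with
the 150–200 mV estimates for strongly lit leaves once the feedback is
released in low-conductivity genotypes. Without the feedback (`npq_feedback
= 0`) the steady state has the closed form `pmf = pmf_dark + v_in/g_H+`,
which the tests exercise.

**Partitioning and spikes.** The membrane is a capacitor: every increment
of pmf lands first on Δψ, then a single counter-ion flux with time constant
`counterion_tau_s` (20 s, config-exposed; only its existence is
mechanistically motivated) relaxes Δψ toward the steady partition

    Δψ_target = f_dark · pmf_dark + f · (pmf − pmf_dark),

with `partition_fraction_dpsi` f = 0.5 by default (observed range
0.20–0.60). Every upward light step therefore produces a transient Δψ
"spike" that decays over tens of seconds — the central mechanistic feature
under study. Integration uses an exponential (exact-relaxation) update per
step, so any `dt` is stable; `dt` need only resolve the schedule.

**Q_A redox poise.** q_L, the oxidized fraction of Q_A, is a saturating
function of irradiance alone: `q_L = q_L,min + (1 − q_L,min)/(1 + I/I_qL)`
(I_qL = 300). Photosynthetic-control feedback on q_L is deliberately not
modeled.

## Light schedules

Three day types span one photoperiod (16 h default): constant
(100 µmol m⁻² s⁻¹), sinusoidal (multiplicative ramp 39 → 500 and back),
and fluctuating (the sinusoidal baseline with each 30-min slot replaced by
2× baseline for 15 min, 1.5× for 12 min, then baseline — peaking at 1000).
The ramp ratio is exact, `r = (peak/start)^(1/n)`; the peak is held across
midday (two steps per half-day), which for the default day gives n = 14
increments and r ≈ 1.20, and makes the schedule mirror-symmetric about
midday. The precise sub-slot timetable of the fluctuating day is a declared
convention built from the verbal rule (2× after 15 min, 1.5× for 12 min,
cycle repeated).

## Synthetic spectroscopy

**ECS.** The 520 nm channel carries `ecs_per_mV · Δψ` (times chlorophyll
per area) plus a slow shared drift; 505 and 535 nm carry the drift plus a
wavelength-linear term, so the (−½, 1, −½) deconvolution cancels both
exactly. During a dark interval the signal decays first-order at `g_H+`
from its light level and inverts below the dark baseline by an amount
proportional to the standing light-driven ΔpH (the proton efflux
transiently reverses the field). The slow counter-ion recovery of the
inversion is *not* modeled inside the ≤ 2–3 s window — over such windows it
would change the signal by ~1 % and would make the decay multi-exponential;
this is also why the partition estimator's fallback baseline is the
pre-illumination dark level (or a flagged zero reference), not an asymptote
fit.

**Fluorescence.** Quenching acts multiplicatively on F_M at fixed F₀:
F_M′ = F_M/(1 + q_E + q_I) and F_M,rec = F_M/(1 + q_I), so the
Stern–Volmer estimators `q_E(SV) = F_M/F_M′ − F_M/F_M,rec` and
`q_I = F_M/F_M,rec − 1` invert the generator exactly, and
q_E(SV) + q_I = NPQ. F_S is back-solved from the target q_L given F₀′
(itself the standard estimate `F₀/(F_V/F_M + F₀/F_M′)`). q_E follows a Hill
curve in lumen pH (pK 6.0, cooperativity 2), re-zeroed at the dark-adapted
lumen pH so a dark leaf has exactly zero q_E and rescaled to saturate at
`qe_max` = 3.5 — the ceiling observed for the quenching response. q_I grows
linearly with the damaged-PSII fraction (`qi_per_damage` = 2). Whether
damage expresses as F_M loss at fixed F₀ or as F₀ rise is not constrained
by the measurements modeled here; F_M loss is the package's convention.

**Photoinhibition.** The damaged fraction accrues at
`damage_coeff · v_r · active` with v_r from the recombination model
evaluated along the simulated (q_L, Δψ) trajectory, and repairs first-order
at `repair_rate` (2 × 10⁻⁴ s⁻¹ ≈ 0.7 h⁻¹) unless lincomycin blocks
translation. `damage_coeff` = 10⁻⁴ inactivations per recombination event is
a convention absorbing the ¹O₂ yield per triplet and the hit probability
per ¹O₂; with it, a wild-type leaf at 1000 µmol m⁻² s⁻¹ loses F_V/F_M with
a rate constant of ~0.3 h⁻¹ under lincomycin, in the physiological range.
Under constant conditions the normalized F_V/F_M decays as a single
exponential (after the initial Δψ-spike transient, which in low-g_H+
genotypes at harsh dark→light steps can itself destroy a large PSII
fraction — the mechanism in miniature).

## Recombination model and calibration

`recombination_rate` implements `v_r = k_r (1 − q_L) 10^(w·Δψ/60)` with
k_r = 0.3 s⁻¹ and 60 mV per decade (0.06 eV). The printed form of the
equation carries a minus sign in the exponent, which contradicts both the
accompanying physics (the field *lowers* the stabilization energy ΔE_stab,
accelerating recombination) and the observed positive q_I–Δψ correlation;
the package defaults to the physical sign and retains an `as_printed`
option, recording the convention in every estimate. The energy-gap form
`v ∝ 10^(−ΔE_stab/0.06)` with ΔE_stab lowered by Δψ/1000 eV is identical to
machine precision (property-tested); the zero-field ΔE₀ is never needed
separately because it is absorbed into k_r. The dielectric weight w
defaults to 1 (the full field acts on the Pheo→Q_A span); a smaller span
can be configured but is not applied by default.

Calibration: one saturating single-turnover flash deposits ~40 mV, so
`mV = ECS · 40/flash_amplitude`. The default dark Δψ constant is the
printed 60 mV (112 mV × 0.5 rounded); the exact product is also exposed.
With the printed inputs the steady-state light-driven Δψ range is
(30, 120) mV and the transient bounds (150, 260) mV.

`qi_association` is an additive two-predictor OLS ANOVA (q_I ~ ECS_ss +
ECS_inv) with Type II sums of squares — the type is the package's choice,
appropriate for unbalanced continuous predictors; a normal-equations oracle
cross-checks the F statistics in the tests.

## The back-reaction simulator

Three lumped states: A = S₂Q_A⁻, B = S₂[P⁺Pheo⁻], G = ground, with A⇌B
equilibrium `K = K0 · 10^(f·Δψ/60)` and decay from B at k_R3 (the
triplet-forming route; direct P⁺Pheo⁻ recombination and P* repopulation are
lumped into its non-triplet branch since no separate rates are available).
The direct Q_A⁻→P⁺ route k_R1 is field-independent by default (it is
already strongly driven and sits in the Marcus inverted region, so more
driving force would slow, not speed it) and zero by default. No rate inside
the radical pair is printed anywhere, so the defaults are conventions tuned
to one constraint: `k_R3 · K0 = 0.3 s⁻¹` (K0 = 5 × 10⁻⁴, k_R3 = 600 s⁻¹,
equilibration k_eq = 10⁶ s⁻¹ ≫ all decay). With K ≪ 1 and fast
equilibration the decay is single-exponential at
`k_R1 + k_R3·K0·10^(f·Δψ/60)`, which the simulator matches within 1 % for
Δψ ≤ 60 mV (the residual is the O(K) correction to the rapid-equilibrium
limit, ~1 % per decade of field).

Integration is exact piecewise-constant matrix-exponential propagation of
the 4-state linear system (G is split by route of arrival), so occupancies
are conserved to machine precision and stiffness is irrelevant; `dt` only
sets the output grid and the resolution of a time-varying Δψ(t). The
initial rate is the exact conditional decay flux after A⇌B
pre-equilibration (t = 20/k_eq), making the dt-convergence property exact
by construction. The ¹O₂ yield is (share of decay via the triplet route) ×
`triplet_branch` (0.7, the dominant-route reading) × `o2_quench_yield`
(0.5, convention) — a *relative* yield per decayed center, not an absolute
photon count. The ionophore comparison runs the same scheme under
`Δψ(t) = Δψ₀ e^(−t/τ)` vs Δψ = 0 and reports the initial-rate ratio and
the ratio of times to half-maximal A.

## The screen

`run_screen` simulates each genotype under each daily schedule (default
integration step 2 s — exact-relaxation updates make this accurate for the
20 s partitioning dynamics), reads quenching parameters at the end of each
light condition (hourly on the constant day), and derives per-genotype
g_H+, ECS_t/ECS_ss/ECS_inv through the full trace-synthesis → deconvolution
→ DIRK-fit path. Measurement replicates (3, with 5 % multiplicative
scatter from one seeded generator) feed Welch t-tests vs the wild type
(per-line, with a labeled Benjamini–Hochberg column added) and the q_I
association ANOVA; log₂ fold changes are computed on the deterministic
phenotype so a wild-type clone is exactly zero. Photoinhibition rate
constants come from a 3 h lincomycin course at 1000 µmol m⁻² s⁻¹ fitted to
`y = y∞ + (1−y∞)e^(−kt)`. Genotype tables are sorted by ascending measured
g_H+ with lexicographic tie-breaks; all tables carry the config hash and
seed.

## What the synthetic data do not show

Passing the round-trip tests shows the estimators invert the generator's
mechanisms at realistic noise; it does not validate the mechanisms against
leaves. Known idealizations: a single well-stirred thylakoid pool (no
granal heterogeneity), additive Gaussian noise (no 1/f drift, no baseline
steps), no 535 nm scattering signal, no chloroplast movement, no S-state
cycle beyond S₂, damage expressed only as F_M loss, and q_L decoupled from
the pmf. Problem sizes in the tests (trace lengths of 10³–10⁴ samples,
100-seed recovery studies, 1000-seed null calibration, a five-genotype
screen) were chosen to characterize the estimators' error distributions at
the precision asserted.

## Numerical choices

Exponential fits: log-linear initialization, then `scipy.optimize.curve_fit`
nonlinear least squares; a fit fails explicitly (`FitError`) for windows
with fewer than 10 samples, flat or rising signals, non-positive amplitude
or time constant, or amplitude below 3× the residual RMSE. Windows are
half-open `[start, end)` seconds, trace indexing 0-based. The dark-interval
minimum is taken from a 5-sample moving average to tame the noise bias of
the min statistic; negative quenching and negative flash-pair activities
are flagged, never clipped; a missing ECS inversion clamps ECS_inv to zero
with a flag (conservation ECS_t = ECS_ss + ECS_inv then intentionally does
not hold and the flag says so). Deconvolution weights default to
(−½, 1, −½) and are config-exposed and recorded in output metadata, since
only the three wavelengths, not the coefficients, are fixed by the
measurement design.
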