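# pmfield

Analysis toolkit for the proton circuit of photosynthesis and its dark side:
how the electric-field component (Δψ) of the thylakoid proton motive force
(*pmf*) accelerates photosystem II charge recombination and photodamage.

The *pmf* built up across the thylakoid membrane during photosynthesis is
the sum of an electric field and a pH gradient, *pmf* = Δψ + ΔpH. Lumen
acidification (ΔpH) drives the photoprotective quenching q_E, but the Δψ
part destabilizes the charge-separated states inside PSII: it shifts the
equilibrium for sharing electrons between Q_A⁻ and pheophytin toward the
P⁺Pheo⁻ radical pair, whose recombination forms the chlorophyll triplet ³P
and, with O₂, the damaging singlet oxygen ¹O₂. The recombination rate from
the S₂Q_A⁻ state is modeled as

    v_r = k_r · (1 − q_L) · 10^(Δψ_light−dark / 60 mV)

with k_r = 0.3 s⁻¹ the intrinsic zero-field rate at fully reduced Q_A,
1 − q_L the reduced-Q_A fraction from fluorescence, and one decade of rate
per 60 mV of field (0.06 eV per decade). Plants with impaired ATP synthase
proton conductivity (g_H⁺) run a higher *pmf* and a higher Δψ, and fluctuating
light drives transient Δψ spikes even in the wild type — both conditions
this package quantifies and simulates.

It is written for researchers doing spectroscopic phenotyping of
photosynthesis: it generates realistic synthetic data (so every estimator is
testable against known ground truth), quantifies the standard measurements,
and simulates the PSII back-reaction kinetics.

## What is in the box

| module | contents |
| --- | --- |
| `pmfield.schedules` | constant / sinusoidal / fluctuating daily light schedules |
| `pmfield.params`, `pmfield.synth` | per-genotype physiology and seeded synthetic ECS / fluorescence / photoinhibition traces |
| `pmfield.ecs` | three-wavelength ECS deconvolution, DIRK first-order fits (g_H⁺, ECS_t), Δψ/ΔpH partitioning (ECS_ss, ECS_inv), flash-pair PSII activity, P700⁺ reduction half-times |
| `pmfield.pam` | saturation-pulse parameters: F_V/F_M, Φ_II, LEF, Stern–Volmer q_E and q_I, q_L, daily integrals, log₂ fold changes |
| `pmfield.recombination` | the field-dependent v_r model, ECS→mV flash calibration, Δψ range arithmetic, two-way ANOVA of q_I on the *pmf* components |
| `pmfield.simulator` | kinetic state model of the PSII back-reaction routes with field-modulated equilibrium and relative ¹O₂ yields |
| `pmfield.screen` / `pmfield.cli` | end-to-end multi-genotype screen and the `pmfield` command line |

The `analysis/` directory holds numbered narrative drivers
(`01_light_schedules.py` … `07_genotype_screen.py`) that run each stage and
write their tables under `results/`.

## Worked example

Recover a genotype's proton conductivity and *pmf* partition from a
synthetic dark-interval relaxation (DIRK) trace, then convert the
steady-state field to mV and a recombination rate:

```python
import pmfield as pf

params = pf.PlantParams()                       # wild type: g_H+ = 20 s^-1
ch = pf.characterize_genotype(params, irradiance=500.0)
mv = pf.calibrate_ecs_to_mv(ch["ecs_ss"], pf.Calibration())
ql = float(params.ql_from_irradiance(500.0))
v_r = pf.recombination_rate(ql, mv).v_r
print(ch["g_H_plus"], ch["fraction_dpsi"], mv, v_r)
```

This prints (to four figures)

```
g_H+ measured        20.00 s^-1     # true 20: DIRK decay time constant inverted
fraction dpsi        0.5000         # true 0.5: ECS_ss / ECS_t
light-driven dpsi    31.39 mV       # flash calibration: 40 mV per flash amplitude
v_r                  0.5629 s^-1    # 0.3 * (1 - 0.4375) * 10^(31.39/60)
```

The steady-state light-driven Δψ falls in the expected 30–120 mV window
(150–200 mV of light-driven *pmf* at Δψ fractions 0.20–0.60), and the
`python analysis/06_psii_decay_simulation.py` driver shows the kinetic
simulator reproducing the analytic Boltzmann factor: a 40 mV field raises
the initial S₂Q_A⁻ decay rate 4.6-fold (~5-fold) relative to an
ionophore-uncoupled membrane.

Running the screen (`python analysis/07_genotype_screen.py`) over a panel
spanning 30–120 % of wild-type g_H⁺ produces the causal chain the package
is about: lower g_H⁺ → larger ECS_t and ECS_ss → larger modeled v_r →
faster photoinhibition, with q_I associating with the Δψ axis
(F = 30, p = 1.4 × 10⁻⁴) and not the ΔpH axis (F = 0.16, p = 0.70) in the
default synthetic panel.

## Command line

```sh
pmfield simulate --day-type fluctuating --out-dir out/   # synthetic data
pmfield dirk --trace out/ecs_trace.csv --light-window 300:380 \
        --dark-window 380:383 --chl 20
pmfield pam --trace out/fluor_trace.csv --par 300
pmfield recombination --ql 0.3 --dpsi-mv 60
pmfield simulate-psii --dpsi0 40
pmfield screen --seed 1 --out-dir screen_out/
```

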