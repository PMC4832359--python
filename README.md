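# hpkinetics

Kinetic modeling of hyperpolarized [1-¹³C]pyruvate dynamics in the perfused
heart: simulation and maximum-likelihood fitting of a **second-order,
cofactor-coupled** reaction model for the conversion of pyruvate to lactate
(LDH), alanine (ALT) and bicarbonate (PDH), alongside the traditional
**first-order** model, plus a synthetic multi-heart cohort generator.

## The problem

Dynamic ¹³C spectroscopy after a hyperpolarized pyruvate bolus yields four
signal-time curves — P\*(t), L\*(t), A\*(t), B\*(t) — that are usually fit
with first-order exchange models (modified Bloch equations) whose rate
constants are assumed constant during the experiment. But the bolus is
supra-physiological: it can transiently deplete the enzymes' cofactor pools
(most importantly mitochondrial NAD⁺, consumed by the one-way PDH flux), so
the apparent rate "constants" drift during the acquisition.

`hpkinetics` implements a mass-conserving model in which every hyperpolarized
pool relaxes into an MR-invisible pool of the same metabolite and each
reaction rate is a *pseudo* rate constant

    k′_PL(t) = k_PL·NADH_c(t),  k′_LP(t) = k_PL·NAD_c(t),
    k′_PA(t) = k_PA·Glu(t),     k′_AP(t) = k_PA·αKG(t),
    k′_PB(t) = k_PB·NAD_m(t),

the product of a true second-order constant and the instantaneous
(non-hyperpolarized) cofactor concentration. The bolus is a gamma-variate
input U\*(t) = k_in (t−t_arr)^δ e^{−β(t−t_arr)}; hyperpolarized pools decay
with effective rates r₁ = 1/T₁ − ln(cos θ)/T_R that fold the RF sampling loss
into the relaxation. The 15-state ODE system conserves total metabolite mass
and all three cofactor pair sums exactly.

Fitting maximizes a Gaussian likelihood with a separate unknown variance per
channel; profiling out the variances leaves the cost

    cost = Σ_channels log SSE_channel

minimized over rates, T₁s, bolus parameters and initial cofactor pools by
seeded Latin-hypercube multistart over bounded trust-region least squares
(see `docs/methods.md`). Primary outputs are the pre/post-injection pseudo
rates — only the products k·Co(0) are structurally identifiable — per-channel
R², and first- vs second-order comparisons with cohort mean ± SEM and
Student's t statistics.

## Worked example

```python
import hpkinetics as hp

sched = hp.AcquisitionSchedule()            # T_R = 2 s, θ = 10°, 90 spectra
preset = hp.GLUCOSE_ONLY                    # glucose-only heart group
inp = hp.calibrate_input_amplitude("second_order", preset["second_order"],
                                   preset["relaxation"], sched, hp.InputParams())
ts, traj = hp.simulate("second_order", preset["second_order"],
                       preset["relaxation"], sched, inp)
data = hp.normalize(ts)                     # unit pyruvate maximum

est = hp.KineticsFitter(model_kind="second_order", n_starts=16, random_state=1)
est.fit(data)
print({k: round(v[0], 4) for k, v in est.pre_post_.items()})
print(round(est.relax_.T1_pyruvate, 1), round(est.cost_, 1))
```

prints

```
{'k_PL': 0.082, 'k_LP': 0.164, 'k_PA': 0.005, 'k_AP': 0.01, 'k_PB': 0.075}
76.7 -126.2
```

i.e. the fit recovers the generating pre-injection pseudo rates (in s⁻¹:
pyruvate→lactate 0.082, →alanine 0.005, →bicarbonate 0.075, with the reverse
LDH/ALT rates at twice the forward values) and the pyruvate T₁ of 76.7 s; the
cost −126.2 is the numerical floor of a noiseless fit (four channels at the
SSE floor). The fitted pseudo-rate time courses (`est.pseudo_rates_`) show
k′_PB(t) collapsing toward zero as mitochondrial NAD⁺ is consumed, while the
reverse rates k′_LP, k′_AP rise — the signature that distinguishes the
second-order from the first-order model, which fits the same bicarbonate
curve visibly worse.

The same pipeline is scriptable:

```bash
hpkinetics simulate --group glucose --outdir out/        # CSV + truth JSON
hpkinetics fit out/data.csv --model second_order --seed 1
hpkinetics cohort --n 5 --seed 7 --group pyruvate        # synthetic cohort
hpkinetics physics dilution 50 1 14                      # 3.33333 mM
hpkinetics physics polarization 20000                    # 0.155843 (15.6%)
```

## Layout

- `hpkinetics.model` — domain types, ODE right-hand sides, bolus input,
  effective relaxation, pseudo-rate reduction
- `hpkinetics.simulate` — forward solution, noise, normalization, cohorts
- `hpkinetics.fit` — `KineticsFitter` estimator, cost/R², pre/post rates,
  model comparison, cohort statistics
- `hpkinetics.utils` — dilution and DNP polarization arithmetic
- `hpkinetics.io` / `hpkinetics.cli` — CSV/JSON/YAML I/O and the CLI
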