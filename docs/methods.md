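# Methods

## Model

The package describes the fate of a hyperpolarized [1-¹³C]pyruvate bolus in
an isolated perfused heart through four reactions: reversible
pyruvate↔lactate exchange (LDH), reversible pyruvate↔alanine exchange (ALT)
and a one-way pyruvate→bicarbonate flux (PDH followed by carbonic-anhydrase
equilibration, modeled as a single step). Every metabolite exists as a
hyperpolarized, MR-visible pool (P\*, L\*, A\*, B\*) and a non-polarized,
MR-invisible pool (P, L, A, B); the starred pools feed their invisible twins
at the effective relaxation rate

    r₁ = 1/T₁ − ln(cos θ)/T_R,

which folds the magnetization consumed by the repeated small-flip-angle
pulses into a continuous decay (no discrete per-pulse bookkeeping). Because
polarization loss moves signal between pools of the *same* metabolite, total
metabolite mass is conserved; the invisible pools keep reacting.

In the **second-order** variant each reaction rate is a pseudo-first-order
rate constant: the product of a true second-order constant and the
instantaneous concentration of the cofactor the enzyme consumes,

    k′_PL(t) = k_PL·NADH_c(t)   k′_LP(t) = k_PL·NAD_c(t)
    k′_PA(t) = k_PA·Glu(t)      k′_AP(t) = k_PA·αKG(t)
    k′_PB(t) = k_PB·NAD_m(t)

with six freely varying cofactor pools (cytosolic NAD⁺/NADH, Glu/αKG,
mitochondrial NAD⁺/NADH) whose pair sums are exactly conserved by
construction. These pools are phenomenological: no enzyme–cofactor binding
(Michaelis–Menten saturation) or membrane transport is modeled, so pool
sizes are arbitrary units, not free cofactor concentrations. PDH is coupled
to mitochondrial NAD⁺ by default — the flux consumes NAD⁺, so k′_PB(t) is
non-increasing, which is what drives the characteristic flattening of the
bicarbonate curve; a `pdh_cofactor="nadhm"` switch couples it to NADH_m
instead (that coupling makes k′_PB *increase* and is retained only for
comparison). The **first-order** variant freezes the cofactor pools: the
five rate constants are time-independent, which is the traditional
modified-Bloch-equation treatment.

The bolus enters the visible pyruvate pool as a gamma-variate rate
U\*(t) = k_in(t−t_arr)^δ e^{−β(t−t_arr)}, zero before arrival. Its relaxed
counterpart U(t) accumulates as dU/dt = β·U\*(t) and is added, literally, to
the invisible-pyruvate balance (`input_term="literal"`); since that places a
pool value in a rate equation, a `conservative` variant that adds β·U\*(t)
(a rate) instead is available. The choice only affects the invisible pools'
growth rate and, through cofactor consumption, the depletion timescale; the
fit is internally self-consistent either way, and the literal form is the
default because it is the published formulation of this model family.

The state vector has 15 components: 8 metabolite pools, 6 cofactor pools and
the accumulated relaxed input. Inside the right-hand side, cofactor values
are clipped at zero only where they multiply a rate constant (so a
marginally negative excursion from the integrator cannot flip a flux sign);
the raw states are integrated and reported unclipped.

## Parameters and defaults

| parameter | meaning | default | why |
|---|---|---|---|
| T_R | repetition time | 2 s | study acquisition interval |
| θ | flip angle | 10° | study excitation pulse |
| n_points | spectra per injection | 90 | spans the ~3 min visible dynamics |
| t_arrival | bolus arrival | 10 s | bolus reaches the heart shortly after acquisition start |
| δ, β | gamma-variate shape/decay | 2.0, 0.07 s⁻¹ | peak ≈ 29 s after arrival, decayed by the end of acquisition — the study's arrival-window shape |
| k_in | bolus amplitude | calibrated | scaled so the noiseless pyruvate maximum is 1 (normalized units) |
| k_PL, k_PA, k_PB | second-order constants | 0.082, 0.005, 0.075 (glucose group); 0.034, 0.0029, 0.0059 (pyruvate group) | group mean pre-injection pseudo rates under the unit-pool gauge below |
| T₁ (P, L, A, B) | relaxation times | 76.7/44.3/60.0/50.5 s (glucose); 76.0/40.2/68.0/73.4 s (pyruvate) | group mean fitted values |
| first-order k | rate constants | 0.083/0.007/0.016 s⁻¹ forward (glucose); 0.041/0.003/0.013 (pyruvate) | group mean first-order fits |
| noise SD | per channel | 0.5% of pyruvate max | typical peak-integral noise; configurable |
| between-heart CV | per parameter | √5 × (SEM/mean) of the group values | so an n = 5 cohort reproduces the reported SEM magnitudes |

**Gauge convention.** Only the products k·Co(0) — the pre-injection pseudo
rates — are structurally identifiable, so the generator fixes each *forward*
cofactor pool at 1 at bolus arrival; the second-order constants then equal
the pre-injection pseudo rates numerically. The reverse pools (NAD_c, αKG)
default to 2, making each reverse pseudo rate twice its forward partner —
reverse rates exceeding forward rates is the qualitative pattern the fits
show, and no tabulated reverse values exist to pin them more precisely. The
unit-pool gauge also sets the depletion timescale; with it, the glucose-group
defaults drive mitochondrial NAD⁺ to exhaustion during the bolus
(k′_PB(Post) ≈ 0) while the LDH couple only re-equilibrates partially — the
regime the second- vs first-order comparison is about.

## Fitting

The four channels are fit simultaneously. With independent Gaussian noise of
unknown per-channel variance, maximizing the likelihood profiled over the
variances is equivalent to minimizing

    cost = Σ_c log SSE_c ,

each channel SSE floored at N·ε_machine so a perfect fit has the finite,
documented cost 4·log(N·ε). Free parameters: the rate constants (plus six
initial cofactor pools for the second-order model), the four T₁s, and the
four bolus parameters — 17 (second-order) or 13 (first-order) in total.
Bounds are generous physiological envelopes: rates ∈ [0, 10] s⁻¹-equivalents,
T₁ ∈ [5, 150] s, t_arrival ∈ [0, 60] s, δ ∈ [0, 10], β ∈ [0.01, 5] s⁻¹,
pools ∈ [10⁻⁶, 10³].

Optimization is a seeded Latin-hypercube multistart (default 16 starts) over
a bounded trust-region-reflective least-squares core, with four structural
elements that the bare multistart needs to be reliable on this landscape:

1. **Log coordinates.** Rates, pools and amplitudes are optimized as
   logarithms (linear for T₁, t_arrival, δ); starts are drawn log-uniformly.
   The rate/pool valleys are badly conditioned on the linear scale.
2. **Staged warm-up.** Each start first fits the bolus parameters and the
   pyruvate T₁ against the pyruvate channel alone, then releases everything.
3. **Nested-model start.** For the second-order fit, one extra structured
   start is built from a quick first-order prefit (pseudo rates at arrival
   set to the first-order constants under the unit-pool gauge). First-order
   fits are cheap and land near the second-order basin.
4. **Reweighted polish.** The least-squares core minimizes Σ_c w_c·SSE_c;
   iterating w_c ← 1/SSE_c makes its fixed points the stationary points of
   the profiled-ML cost. The best few exploratory starts get several
   reweighting rounds; steps are accepted only if they lower the true cost.
   Exploration integrates at rtol 10⁻⁶, polish at 10⁻⁸ — at the looser
   tolerance the cost landscape bottoms out at integration noise, which
   would otherwise masquerade as shallow minima. Polishing stops early once
   the cost reaches the perfect-fit floor.

Everything is deterministic given `random_state`. Goodness of fit is the
per-channel coefficient of determination about the channel mean (undefined,
reported as NaN, for a constant channel). Pre/post pseudo rates are k′
evaluated at t_arrival (where cofactors still sit at their initial pools, so
Pre = k·Co(0) exactly) and at the last acquisition time. Raw k and Co(0) are
exposed but documented as non-identifiable separately; reported primary
outputs are the products. The known degeneracy between reverse rates and
relaxation rates is reproduced and tested: the flattest curvature direction
of the cost in the (k_LP, T₁L) plane is far softer than the curvature along
k_PL.

Cohort statistics: per-parameter mean and SEM (= SD/√n) across per-heart
fits, and a two-sample two-tailed Student's t test (pooled variance by
default, Welch by flag) for between-group comparisons.

## Synthetic data

The generator emulates the study's acquisitions: 2 s repetition time, 10°
flip angle, 90 spectra, signals normalized to the pyruvate maximum of each
experiment, independent additive Gaussian noise with a separate SD per
channel, and n-hearts-per-group cohorts with per-heart parameters drawn
log-normally (mean-preserving) around the group truth. Log-normal draws keep
rates positive; the default CVs are sized so an n = 5 cohort reproduces the
reported SEM magnitudes.

What it does **not** emulate: spectral line shapes, phasing and baseline
errors (the pipeline consumes integrated peak areas); discrete per-pulse Mz
loss (folded into r₁); bolus-shape variability between injections beyond the
gamma-variate family; physiological drift or motion; any correlation
structure in the noise. Passing round-trip tests therefore demonstrates that
the estimator recovers the generating kinetics under the model's own
assumptions — not that those assumptions hold for a given spectrometer or
preparation.

## Numerical choices

- Integrator: LSODA (via `scipy.integrate.odeint`) with a numba-compiled
  right-hand side; rtol 10⁻⁸/atol 10⁻¹⁰ for simulation, 10⁻⁶/10⁻⁹ inside
  exploration, 10⁻⁸ for polish and reported fits. The state is exactly
  constant before t_arrival, so integration starts there (this also keeps
  the gamma-variate kink off the interior of the first step).
- A hard cap of 500 internal steps per output interval turns pathological
  parameter drafts (which the multistart legitimately visits) into fast,
  penalized failures instead of multi-second integrations.
- Cofactor clipping at zero applies only inside rate products, as above.
- SSE floor: N·ε_machine per channel; the same floor caps the IRLS weights.
- Gamma-variate at δ = 0: the value at t_arrival is k_in (0⁰ = 1), matching
  the exponential limit; the input is identically zero before arrival.
- Ties in multistart ranking are broken by start order (stable sort), so a
  fixed seed reproduces fits bit-for-bit.
- Degenerate inputs: all-constant metabolite channels are flagged in the
  convergence record (`degenerate_channels`) and drive the corresponding
  rates to their lower bounds; a non-positive pyruvate maximum is a
  normalization error.

## Problem sizes used in the checks

The recovery checks fit 90-point noiseless series with 16 multistarts (one
second-order fit per study group plus one first-order round trip); the
integrator cross-check compares a 60 s window against a fixed-step
fourth-order Runge-Kutta oracle at 1 ms steps; Monte-Carlo checks of the
cohort generator use up to 400 parameter draws; the noisy-recovery spot
check uses one 0.5%-noise series. These sizes were chosen so the full suite
exercises every claim at the study's own acquisition geometry.

## Known limitations

- Reverse rate constants and T₁s are strongly correlated; only the forward
  pseudo rates and (in the second-order model) the T₁s are well determined.
  The package reports reverse rates but they inherit large uncertainty.
- With PDH coupled to NAD_m and no regeneration term, mitochondrial NAD⁺
  can only fall during an injection; recovery between injections is outside
  the model.
- The literal input term makes the invisible pyruvate pool grow quickly
  late in the acquisition; mass conservation of the metabolite block holds
  exactly only for k_in = 0 (the bolus is an external source).
- NADH_m(0) (under the default coupling) does not influence the observables
  and is reported only as drawn/fitted, carrying no information.
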