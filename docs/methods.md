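# Methods

## Hemodynamic model

The generator is a lumped-parameter circulation with one ventricle:

- **Ventricle.** Time-varying elastance, `P_lv(t) = E(t)·(V − V0)` with
  `E(t) = Emin + (Emax − Emin)·φ(t/T)`, where φ is a double-Hill activation
  (shape exponents 1.9 and 21.9, time constants 0.269·T and 0.452·T,
  normalized to peak exactly 1). The double-Hill is the standard smooth
  activation for elastance models; its constants are fixed in the engine and
  are not fitted. V0 (volume at zero generated pressure) is constant per
  animal.
- **Valves.** Diode resistances: mitral inflow from a constant venous
  pressure source (R_mv = 0.03 mmHg·s/mL), aortic outflow into the arterial
  compartment (R_av = 0.04 mmHg·s/mL).
- **Afterload.** Two-element Windkessel: compliance Cart (mL/mmHg) and
  systemic resistance SVR (mmHg·s/mL) draining to right atrial pressure. A
  two-element model is the smallest one that reproduces the observed loop
  shapes, including the triangular loop under full pump support.
- **Pump.** Continuous (non-pulsatile) axial flow from ventricle to aorta
  with a linear head-flow curve: `Q = clip(Qmax·level − k·(P_ao − P_lv),
  0, Qmax·level)` with Qmax = 3.5 L/min and k = 0.02 L/min/mmHg, so the pump
  delivers ~2.6 L/min against a 45 mmHg head and derates toward ~1.7 L/min
  against the high afterload of the phenylephrine stage.

Integration is explicit Euler at 8 substeps per output sample (2 kHz
internally at the default fs = 250 Hz), jitted with numba; 20 settling
cycles precede every recording, after which the net volume change per cycle
is below 0.1 mL. The cycle length is snapped to an integer number of output
samples so that every recorded beat samples the waveform at identical
phases; this makes noise-free end-systolic points exactly collinear and
parameter-recovery contracts exact rather than discretization-limited.
`Ees_true` in the attached ground truth is accordingly defined as the
maximum of the *sampled* elastance (0.1% below the continuous Emax at
250 Hz).

## Stage presets (the study conditions)

Seven presets parameterize the experimental stages. They were calibrated
once against the published stage means — contractility and diastolic
stiffness against the Ees/LVESP/LVESV/LVEDP quadruples (which imply a
constant V0 ≈ 17 mL in both the healthy and the shocked column), resistances
and filling pressures against MAP/RAP and the flow implied by the Fick
balance — and are not revisited. Key values (Emax mmHg/mL, HR bpm, SVR
mmHg·s/mL): baseline 1.43/82/0.93; shock 0.36/81/0.90 (stiffer, venodilated,
anemic); pump support 0.74/75/0.90 with pump level 1; epinephrine
1.10/90/0.95; dopamine 1.45/104/0.85; norepinephrine 1.00/78/1.25;
phenylephrine 0.74/107/1.85 with raised filling pressure (venoconstriction)
and hemoconcentration. Drug presets are phenomenological parameter shifts at
the stated equipotent doses, not pharmacokinetics. The heart-rate rise under
phenylephrine is encoded as a preset delta without a mechanistic claim.

Between-pig variability is lognormal multipliers (σ: Emax 0.15, Emin 0.10,
SVR 0.12, venous pressure 0.08, Cart 0.10, VO2 0.10, Hb 0.06) plus additive
draws (HR 5 bpm, V0 2.5 mL), chosen so the model's cross-animal dispersion
matches the published 95% CIs (e.g. baseline SW: model SD ≈ 1375 mmHg·mL vs
CI-implied ≈ 1325). Measurement noise: 1 mmHg on pressures and 2 raw units
on conductance volume at the sample level; stage-summary (record-level)
noise of a few percent per variable in the fast tier.

## Oxygen transport

A static Fick balance: `SvO2 = SaO2 − 100·VO2/(1.34·16.114·Hb·CO)` with Hb
in mmol/L and CO in L/min, clamped to [0, 100]; organ venous saturations use
organ VO2 fractions (renal 0.07, cerebral 0.105) over organ flow fractions
(renal 0.20, cerebral 0.12). Arterial lactate rises linearly once oxygen
delivery falls below a critical 400 mL O2/min (slope 0.004 mmol/L per
mL/min). This reproduces the direction and rough size of the perfusion
responses; it has no washout kinetics, so the slow post-shock lactate decay
seen in real animals is not modelled.

## Signal analysis

- **Beat segmentation.** Upstroke crossings of 0.3 × max dP/dt on a
  zero-phase 15 Hz low-passed pressure, separated by ≥ 0.25 s; each crossing
  is traced back to its foot (dP/dt below 10% of threshold) and end-diastole
  is the pressure minimum in a 24 ms window ending at the foot — or the foot
  itself when filling pressure rises monotonically and no interior minimum
  exists. Spans deviating more than 25% from the median length are dropped
  (filter-edge artifacts).
- **End-systole.** The sample maximizing instantaneous elastance
  P/(V − V0). This needs no ejection, so it remains valid for fully
  supported beats whose aortic valve never opens (6/10 animals at the
  default cohort seed).
- **Energies.** SW by the shoelace formula over the cycle's (V, P) polygon;
  PE from the end-systolic point; PVA = SW + PE with the constant V0
  (single-beat construction). Stage summaries average the primitive
  quantities (volumes, pressures, SW, cycle length) over the final 10 s
  window and recompute all derived quantities from those means, so
  PVA = SW + PE and cardiac work = HR × PVA hold exactly in every summary.
- **Calibration readouts.** Per-beat EDV/ESV values are short window means
  (15 samples) at one fixed within-beat offset chosen from the beat-averaged
  waveform — inside the isovolumic contraction and relaxation plateaus —
  rather than per-beat extrema, whose noise bias (several mL at 2 mL sample
  noise) would otherwise propagate through the wash-in regression with a
  ~5-fold extrapolation gain. On noise-free data the fixed offsets keep the
  wash-in (EDV, ESV) pairs exactly collinear, so Vc recovery is exact.
- **ESPVR.** ES selection depends on V0, so the occlusion fit alternates ES
  detection and line fitting to a fixed point (2-3 iterations). A negative
  fitted V0 is clamped to 0 with a warning, since the PE and Ees formulas
  require V − V0 > 0.

## Crossover mixed model

One random intercept per pig, fixed categorical stage, and stage-specific
residual variances (the variability of most variables differs markedly
between shock, support and drug stages), estimated by REML with a custom
fitter (scipy L-BFGS-B on log-variances; per-pig block Cholesky). When the
heterogeneous fit does not converge the model falls back to a pooled
residual variance and logs the downgrade. On balanced data the fixed-effect
estimates equal the stage means, and the homoscedastic special case
reproduces statsmodels MixedLM to three decimals (a test asserts this).

Contrasts vs the pump-alone reference use **pig-level cluster-robust (CR1
sandwich) covariance with t quantiles at n_pigs − 1 degrees of freedom**. On
this balanced design a stage contrast is a paired mean difference across ten
animals: the large-sample normal quantile and the model-based covariance
both undercover in that regime (the diagonal-residual model cannot represent
the negatively correlated pig-by-stage interactions that the nonlinear
between-pig physiology induces), while the robust-t construction is the
paired-contrast small-sample reference. Empirical coverage of the 95% CI for
the dopamine cardiac-work effect is ~92–93% over 200 simulated cohorts,
against the population-average effect estimated by a separate 1000-draw
Monte Carlo. No multiple-testing adjustment is applied (p < 0.05 per
contrast). A period (within-pig order) covariate is available via
`include_period=True` but off by default: only the three blinded stages vary
in position, and phenylephrine's fixed last position makes a carryover term
inseparable from its drug effect.

The leave-one-out sensitivity analysis refits the model excluding each
animal once and reports per-stage effect ranges and sign stability.

## Problem sizes and determinism

Defaults: fs = 250 Hz, 30 s stage recordings (last 10 s analyzed), 12-beat
occlusions at 5%/beat preload decay, 12-beat saline wash-ins with 40% peak
conductivity gain, cohorts of 10 pigs. Monte-Carlo studies use the fast
summary tier (noise-free ODE truth + record-level noise): 200 replicate
cohorts for CI coverage, 100 seeded boluses for Vc recovery, 10 pooled
cohorts for the baseline stroke-work check (reducing the Monte-Carlo error
of the check below single-cohort sampling noise). Every random draw descends
from an explicit integer seed; identical seeds give bit-identical traces,
cohorts and output tables (the pipeline manifest records SHA-256 of every
table).

## What passing tests do and do not show

The generator reproduces the calibrated stage means, the published
confidence-interval widths, the loop-shape phenomenology (leftward
triangular loops under support, rightward shift under phenylephrine) and the
sign pattern of every stage/drug effect. It does **not** contain coronary
circulation, infarct geometry, arrhythmias, a right ventricle, baroreflexes,
or drug kinetics; drug effects are constant parameter shifts. Consequences
visible in the outputs: simulated MAP under phenylephrine overshoots the
published contrast (no reflex buffering), shock-stage SvO2 runs a few points
low in noisy cohorts (convexity of the Fick balance under between-pig
draws), and lactate has no washout dynamics. Parameter-recovery and coverage
results validate the estimators under this model's assumptions — they are
necessary, not sufficient, evidence about behavior on real conductance
recordings.
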