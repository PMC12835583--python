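# Methods

## The model

`rvcirc` simulates the right heart and pulmonary circulation as a
lumped-parameter network with four dynamic compartments — the right
ventricle (RV), pulmonary arteries (PA), pulmonary capillaries (PC) and
pulmonary veins (PV) — bounded by constant right- and left-atrial pressure
sources `P_RA` and `P_LA`.  The states are the four compartment volumes
(mL); all pressures are in mmHg, flows in mL/s, time in s.

- **RV**: time-varying elastance chamber, `P_RV(t) = E(t)·(V_RV − V0_RV)`
  with `V0_RV = 0` by default.
- **Vascular compartments**: linearly compliant Windkessel elements,
  `P_i = (V_i − V0_i)/C_i` for i ∈ {PA, PC, PV}.
- **Connections**: constant resistances with Ohm-analog flow
  `Q = ΔP/R`.  The tricuspid and pulmonic valves are ideal diodes,
  `Q = max(0, ΔP/R)`; the vascular segments are ungated and may carry
  transient reverse flow.
- **Conservation**: `dV_k/dt = Q_in − Q_out` per compartment, so the total
  volume rate equals tricuspid inflow minus venous outflow identically.

### Elastance curve

The activation function is a piecewise raised cosine parameterized by the
time of peak elastance `tmax` and the end of relaxation `tmin`:

    E(t) = Emin + (Emax−Emin)/2 · (1 − cos(π t/tmax))              0 ≤ t ≤ tmax
           Emin + (Emax−Emin)/2 · (1 + cos(π (t−tmax)/(tmin−tmax)))  tmax < t ≤ tmin
           Emin                                                     tmin < t < T

It is continuous, T-periodic, equals `Emin` at the cycle start and along
the diastolic plateau, and peaks at `Emax` at `t = tmax`.  Published model
descriptions in this family state the timing semantics without printing
the closed form; among the standard options (raised cosine, double-Hill)
we chose the raised cosine because it satisfies the stated anchor
constraints exactly and keeps the activation phase C¹ except at the
plateau joints.  A different smooth curve with the same anchors would
change waveform details but none of the structural conclusions.

### Integration

The system is mildly stiff (the open pulmonic valve couples the RV to the
arterial compliance with a millisecond time constant), so we integrate
with LSODA (adaptive, stiffness-switching; `scipy.integrate.odeint`
driver) at `rtol = atol = 1e-6`.  A simulation runs 40 cardiac cycles by
default and reports the final cycle, resampled onto a uniform grid (200
points by default) or onto a caller-supplied measurement grid.  The
periodicity error — the maximum relative state change across the output
cycle — is well below 1e-3 for all physiological parameter sets we
generate; results are insensitive to the initial state, which is seeded
from a resistor-chain pressure profile.  Inside iterative loops
(calibration, screening) the warm-up may stop early once the
cycle-to-cycle state change falls below `stop_tol` (1e-4 by default
there), and calibration additionally reuses the previously converged
end-of-cycle state as the next start; the periodic orbit is the system's
unique attractor, so both shortcuts change only the transient burned, not
the answer.

## Initialization from routine clinical data

A patient's summary (HR, CO, PAWP, mPAP, and optionally RAP, sPAP/dPAP,
RV volumes) determines every baseline parameter algebraically:
resistances from mean pressure drops over CO; unstressed volumes as the
23% / 49% / 28% split of stroke volume over the arterial/capillary/venous
beds; compliances as unstressed volume over mean compartment pressure;
`Emax = P_SysRV/ESV`, `Emin = P_DiaRV/EDV`; timing at 0.2 T and 0.5 T.
Mean PA pressure uses the (2·dPAP + sPAP)/3 estimate, mean LA pressure is
min(PAWP, dPAP), and the PA→LA gradient is split 30/30/40% across the
three beds.  `P_SysRV` sits 0.5 mmHg above systolic PA pressure
(a slight forward valve gradient) and `P_DiaRV` starts at 2 mmHg — both
initial guesses that calibration refines.

Missing optional fields are imputed with documented, configurable
defaults:

- **sPAP/dPAP from mPAP alone**: `dPAP = 0.6·mPAP`,
  `sPAP = 3·mPAP − 2·dPAP`, which returns mPAP exactly under the
  (2d+s)/3 estimate.
- **RAP**: 3.0 mmHg (No PH, isolated post-capillary), 3.2 mmHg
  (pre-capillary, combined).  The low-normal choice is deliberate: the
  tricuspid baseline `Rval_T = (RAP − 2)/CO` sets the diastolic filling
  rate at roughly `(RAP − P_RV,dia)/(RAP − 2) · CO` over about half the
  cycle, so an elevated RAP default makes the *uncalibrated* model's
  cardiac output fall 30%+ short of the measured value, while the
  low-normal default keeps the round trip within 25% for every subject in
  the packaged reference table.  When a measured RAP is available it is
  used as-is; `Rval_T` is calibrated in any case.
- **RV volumes**: `EDV = max(120, SV + 30)` mL, `ESV = EDV − SV`, keeping
  a plausible end-systolic reserve for high-output patients.

Calibration bounds are 1%–600% of baseline for magnitudes and the fixed
windows `tmax ∈ [0.05, 0.35]·T`, `tmin ∈ [0.35, 0.70]·T` for timing.

## Sensitivity screening

Morris elementary-effects trajectories (default r = 20, 8 levels) screen
the twelve resistance/compliance/elastance parameters.  Two design
choices matter:

- **Functional**: effects are computed on the whole final-cycle pressure
  and flow *waveforms* — the elementary effect is the RMS waveform change
  per unit normalized step, relative to the baseline waveform RMS.
  Scalar summaries (cycle-mean pressure, peak flow) are poor screens
  here: compliances barely move a cycle mean and downstream resistances
  barely move a peak flow, so either scalar would discard parameters that
  visibly reshape the signals.
- **Range**: the screen is local, 0.8×–1.25× around baseline — a
  relative-perturbation sensitivity.  Over the full calibration range the
  pulmonic-valve resistance reaches values that visibly distort the flow
  wave, even though around any physiological baseline its influence is
  negligible; a local screen reflects the latter, which is what matters
  for choosing calibration parameters.

Selection ranks parameters by their *combined* influence (the maximum mu*
across the two outputs) and excludes the bottom three, with a sanity
check that each excluded parameter is also in the bottom half of every
per-output ranking.  On the packaged reference cohort's mean baseline
this stably excludes the pulmonic-valve resistance and the capillary and
venous compliances, leaving the nine-parameter calibration subvector
(Rval_T, R_PA, R_PC, R_PV, C_PA, Emax, Emin, tmax, tmin).

## Calibration

The cost blends dynamic and static terms:

    J(θ) = Σ_j (1/Nt)·[(P_PA(t_j) − PAP(t_j))/max PAP]²
         + Σ_j (1/Nt)·[(Q(t_j) − Q_RVOT(t_j))/max Q_RVOT]²
         + 2·[(P_min^model − P_min)/P_min]² + 2·[(P_max^model − P_max)/P_max]²
         + 2·[(Q_max^model − Q_max)/Q_max]²

Each summand's square root is one residual, so the trust-region-reflective
least-squares solver (`scipy.optimize.least_squares`, bounded) minimizes
exactly J.  The optimization restarts from 20 randomized perturbations of
the baseline by default (log-uniform 0.5–2× for magnitudes, uniform
within the window for timing) and reports the minimum-cost start with a
full per-start audit.  Numerical settings: relative finite-difference
step 1e-3, `xtol = ftol = gtol = 1e-10`, at most 400 residual evaluations
per start; a failed simulation returns a constant residual vector worth
J = 1e6 so the optimizer backs away smoothly.  The static anchors are
read through a periodic moving-average window (8% of the cycle) applied
identically to data and model: the anchors stand for clinical
systolic/diastolic readings of the underlying waveform, and a raw
`max()` over noisy samples is upward-biased by roughly 1.5 noise SDs,
which the weight-2 anchor terms would otherwise convert into a 20–30%
parameter bias.  The minimum-pressure normalizer is floored at 1 mmHg to
guard near-zero diastolic pressures.

## PV-loop metrics

From the final cycle: EDV/ESV are the volume extrema, EDP/ESP the RV
pressures sampled at those same instants, SV their difference.  Stroke
work is the area of the (V, P) loop — cyclic trapezoidal quadrature of
the pressure-volume work integral — reported positive for the
physiological orientation (fill at low pressure, eject at high pressure)
and converted to joules with 1 mL·mmHg = 1.33322e-4 J.  Loops that fail
the periodicity tolerance or have negligible stroke volume are refused;
at 200 grid points the quadrature is within 0.2% of an 800-point
reference.

## The synthetic cohort

No patient recordings are distributable, so every downstream stage is
exercised on virtual patients.  Each phenotype preset starts from
group-level target hemodynamics (heart rate, cardiac output, wedge
pressure, mean PA pressure, RV volumes) chosen inside the published
group envelopes, is initialized like a patient, and is then tuned by a
deterministic fixed-point loop (tricuspid resistance → cardiac output;
series vascular resistances → mean PA pressure) until the forward
simulation lands on the targets within 2%.  Patients are drawn around
the preset with multiplicative log-normal spread (8% resistances, 10%
compliances and elastances, 4–5% timing and cycle length, 10–12% atrial
pressures), which reproduces realistic within-group variability —
including occasional low-output or high-pressure outliers.

Observed waveforms pass through a measurement-noise model
`v_obs = v·(1 + ε_m) + ε_a` with i.i.d. Gaussian noise and an optional
uniform circular phase shift.  Defaults: pressure 5% multiplicative +
0.5 mmHg additive (high-fidelity catheter); flow 18% multiplicative +
8 mL/s additive (Doppler VTI × outflow-tract-area flow compounds tracing
and diameter errors and is known to carry 15–20% uncertainty).  Phase
jitter defaults to zero: the emulated signals stand for recordings that
have already been beat-aligned, as clinical preprocessing produces.  We
verified that even a 2% residual misalignment is absorbed by the
optimizer into the elastance timing parameters and biases recovered
parameters by over 50% — worth knowing, but not a sensible default
observation model for aligned data.

What the generator does **not** emulate: beat-to-beat variability,
respiration, arrhythmia, valve regurgitation, measurement drift, and any
model-structure mismatch — the virtual patients are drawn from the same
model family that is fitted to them.  Passing recovery tests therefore
demonstrates identifiability and optimizer correctness under the stated
noise, not robustness to structural error in real recordings.

## Phenotype analysis

Group comparisons use the tie-corrected Kruskal-Wallis test with Dunn's
pairwise z-tests (Holm-adjusted by default; Bonferroni or none are
options).  Model-vs-clinical agreement uses paired t-tests, where a
significant p-value flags *disagreement*.  Separability uses pooled-
covariance LDA with Ledoit-Wolf shrinkage (eigen solver; a fixed λ = 0.5
fallback covers tiny cohorts where the data-driven estimate fails), a 2-D
discriminant projection, and leave-one-out accuracy with standardization
refit inside each fold.  Feature sets: clinical (HR, CO, PAWP, mPAP,
sPAP, dPAP), model-derived (the nine calibrated parameters plus the six
PV-loop metrics), and their union.  For cohort-level separability
studies the model features are taken from the generator's ground truth
(plus PV metrics of the noiseless simulation); calibration fidelity is
established separately by the recovery experiments, and decoupling the
two keeps the separability replicates affordable.

## Reproduction experiment sizes

The bundled experiments (`rvcirc.experiments`, driven by
`scripts/acceptance.py`) use: 50 random parameter draws for the
conservation/gating/periodicity suite; 8 virtual patients (2 per
phenotype) at 5 starts for noiseless recovery; 20 patients (5 per
phenotype) at 5 starts for noisy recovery; 5 screening seeds at r = 20;
a triple-size cohort (75 patients) for the stroke-work ordering; and 20
study-sized cohort replicates for the LDA comparison.  The stroke-work
trend deserves a caveat: the published adjacent group means differ by
only ~6% while realistic within-group spread is large, so at the study's
own group sizes (5/12/5/3) the full ordering reproduces in roughly
two-thirds of cohort draws; at triple size it is stable across seeds.
The triple-size check tests the contrasts the generator encodes rather
than single-draw sampling luck.

## Known limitations

- Open-loop: no systemic circulation or venous return coupling; atrial
  pressures are constant sources.
- Linear elastance and linear compliances; no nonlinear end-diastolic
  pressure-volume relation, no pulse-wave propagation.
- The +0.5 mmHg transpulmonary systolic offset fixes `Rval_P`; it is
  excluded from calibration.
- Identifiability of the individual series resistances (R_PA vs R_PC vs
  R_PV) rests on waveform shape details; under heavy flow noise their
  split wanders while the total stays pinned.
- Phenotype presets are fixtures constructed to honor published
  qualitative contrasts; they are not estimates of any patient's fitted
  values.
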