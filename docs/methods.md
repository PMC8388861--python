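# Methods

## Model structure and assumptions

Both analytes (ENR, CIP) are described by flow-limited, well-stirred
compartment models sharing one pig physiology. Compartments: venous blood,
lung, liver, kidney, muscle, fat, rest-of-body; ENR additionally has a
two-stage gut lumen (stomach → intestine) and a feces pool. The lung sits in
series between venous and arterial blood and carries total cardiac output;
arterial concentration is the lung venous outflow (C_lung/P_lung). Tissue
uptake is perfusion-limited: the venous concentration leaving tissue *T* is
C_T/P_T.

Absorbed ENR (Ka·A_int) enters the liver, so hepatic first-pass metabolism
acts before systemic distribution — consistent with CIP being formed in the
liver. A fixed mass fraction `Frac` of hepatically cleared ENR appears as
CIP in the CIP sub-model's liver; the remainder accumulates in an
"other-metabolites" pool. No molecular-weight correction is applied to the
ENR→CIP conversion; `Frac` is a mass fraction. CIP has no oral input and is
cleared only renally. Plasma protein binding is not modelled separately:
tissue concentrations are compared directly with medium concentrations
(in-vitro/in-vivo free-concentration equivalence is taken as an assumption,
not computed).

Assumptions worth stating plainly: instantaneous tissue equilibration
(flow-limited), first-order absorption and clearances (hence dose
linearity), time-invariant physiology over the 10-day horizon, and tissue
density 1 g/mL so 1 µg/mL ≡ 1 µg/g ≡ 1000 µg/kg.

## Parameters

The packaged default (`enrpbpk/data/pig_enr_defaults.yaml`) describes a
55 kg grower pig. Organ volume and blood-flow fractions are standard swine
PBPK values; cardiac output is QCC·BW^0.75 with QCC = 8.7 L/h/kg^0.75.
Chemical-specific constants are literature-informed for oral
fluoroquinolones in swine rather than fitted to any particular study:
moderate oral absorption (Ka 0.35 /h) with partial fecal loss (Kint
0.15 /h, bioavailability ≈ 0.7), gastric emptying Kst 1.5 /h, hepatic
metabolic clearance KmC 0.22 and urinary clearances KurineC 0.11 (ENR) and
Kurine1C 0.16 (CIP), all in L/h/kg^0.75, and `Frac` = 0.04 (about 4% of
cleared ENR emerges as CIP in the pig). Partition coefficients are high for
a fluoroquinolone (liver/kidney ≈ 7, muscle 2.5, fat 0.8 for ENR), giving a
terminal tissue half-life of roughly 19 h and marker depletion through the
MRLs over 4–7 days — the regime a pig residue study operates in. These
defaults were fixed once on physiological-plausibility grounds; `calibrate`
exists to refit `Ka`, `Kurine1C` and the partition coefficients to an
actual residue dataset (log-scale least squares, an automated surrogate for
manual curve adjustment).

Clearances scale with BW^0.75 by default (exponent exposed in the config).
This matters: with per-kg dosing and *linear* clearance scaling, body weight
cancels from the model to first order and its NSC collapses to ≈ 0.1,
which contradicts the well-established strong BW sensitivity of terminal
tissue residues in growing pigs; with allometric scaling the packaged model
gives |NSC(BW)| ≈ 1.0, the expected behaviour.

Dosing default: 5 mg/kg b.w. twice daily for 5 days (10 doses, last at
108 h), simulated to 228 h or to whatever horizon the analysis needs.

## Numerics

- Integration: `scipy.integrate.solve_ivp` (LSODA), rtol 1e-6, atol 1e-9.
  Each administration is an impulse into the stomach state; the solver is
  restarted at every dose time so no discontinuity is interpolated across.
  An output time equal to a dose time reports the post-dose state.
- Verification: an independent fixed-step classical RK4 integrator
  (`integrate_rk4`) reproduces the adaptive solution to < 1e-3 relative
  error (observed ≈ 1e-6), and mass balance closes to < 0.1% (observed
  ≈ 1e-13) for both analytes at every output time.
- Sensitivity: forward difference at +1% exactly (central differences
  optional). Perturbing BW re-derives every flow, volume and clearance.
  Calibration uses a 1e-3 relative differencing step so the numerical
  Jacobian dominates solver noise.
- Truncated-normal sampling is by rejection (acceptance ≈ 68% at ±1 SD),
  never by clipping, which would pile mass at the bounds. Parameters are
  sampled independently; non-sensitive parameters stay at their calibrated
  values.
- The MC withdrawal day grid is exact multiples of 24 h after the last
  dose; the smallest compliant whole day is reported (curves crossing
  between days are attributed to the later day — conservative rounding-up).
  The default rule is the empirical 99%-of-population count; a stricter
  distribution-free variant (order-statistic upper bound on the 99th
  percentile at 95% confidence) is available via `require_confidence`.
- Tolerance-limit regression: tolerance factors come from the noncentral-t
  distribution with n−2 df and the leverage of the prediction time, not
  from table lookup; the implementation reproduces published one-sided
  K-factor tables (p = 0.99, 95% confidence) to three decimals. Records
  below the LOQ (0.02 µg/mL ≡ 20 µg/kg) are excluded by default; LOQ/2
  substitution is available and recorded in the diagnostics.
- 4PL fitting: `scipy.optimize.curve_fit` on mean-of-batches viability vs
  log10 concentration, top bounded [80, 110]%, bottom [0, 30]%, hill < 0
  (viability decreases with concentration). A fitted IC50 outside the
  tested concentration range is refused unless extrapolation is requested.
- Dose reversal: bisection on the granularity grid (default 1 mg/kg),
  cross-checked against the dose-linearity shortcut threshold/Cmax(1 mg/kg);
  disagreement beyond one step is an error, not a warning.

## Synthetic data: what it does and does not emulate

`generate_residue_study` draws one multiplicative log-normal deviation per
animal (mean-preserving, σ² = ln(1+CV²), default CV 25% — an assumption,
as real inter-animal CVs for this product are not tabulated) around the
model's own depletion curves, flags sub-LOQ values, and adds drug-free
control animals. It emulates the *design* and the *noise structure* of a
slaughter study, not assay recovery, measurement bias, or kinetic model
misspecification — so pipeline tests passing on synthetic data demonstrate
internal consistency (estimators recover what the generator put in), not
field accuracy on real pigs. `generate_viability_plate` back-calculates
absorbances so the viability equation reproduces a chosen 4PL curve plus
additive Gaussian noise (default SD 3.7 percentage points, a realistic
replicate scale for CCK-8 assays).

`end_to_end_fixture` bundles parameters, one study, ENR and CIP plates and
the MRL set, with ground truth (MRL-crossing days of the generating curves,
unit-dose liver Cmax, generating IC50s) attached for regression testing.

## Design choices made where the design was open

- MC withdrawal rule: empirical 99% population count by default; the
  tolerance-bound variant behind a flag (both appear in regulatory
  practice; the count is the standard Monte Carlo reading).
- Liver receives absorbed drug (first-pass) rather than systemic blood;
  configurable only by editing the model, as the alternative breaks the
  CIP formation story.
- The marker residue is ENR+CIP everywhere a limit is applied; single-
  analyte traces remain accessible for fitting and diagnostics.
- Problem sizes: the acceptance run uses n = 1000 virtual pigs (the
  standard batch size for this analysis); tests use 40–100 pigs, which is
  ample for structural checks while keeping the suite fast.

## Known limitations

- Flow-limited tissues cannot represent deep binding pools with distinct
  terminal phases (e.g. melanin or injection-site depots).
- No correlation structure between sampled parameters; a heavy pig is not
  made to have proportionally larger clearance draws beyond the BW scaling
  itself.
- The ±1 SD truncation makes extreme individuals impossible by
  construction; population percentile estimates near the bounds are
  accordingly optimistic.
- The toxicity reversal treats the in vitro IC50 as a bright-line in vivo
  liver threshold; no toxicodynamics, exposure duration, or recovery are
  modelled.
- Withdrawal-time outputs depend on the packaged default parameterization;
  conclusions for an actual product require calibration against its own
  residue study.
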