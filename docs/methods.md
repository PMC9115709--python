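# Methods

`spheropv` implements the quantitative analysis behind a 3D tumor-spheroid
drug-permeability screen: converting spheroid viability readouts into a
per-drug permeability statistic, relating that statistic to molecular
descriptors by multiple linear regression, and cross-referencing it with
classical permeability and drug-likeness criteria.  This note records the
models, conventions, numerical choices and known limitations.

## The permeability value (PV)

Each drug is screened at a fixed concentration (the monolayer IC50) against
three spheroid types: a stromal/cancer co-culture (A:M), a stromal-only
monoculture (ASC) and a cancer-only monoculture (MDA).  Viability is the
treated/control luminescence ratio of an ATP assay, with the control matched
per composition; drug efficacy is

    efficacy = 1 - signal_treated / signal_control

and the permeability value is

    PV = Eff_A:M - (Eff_ASC + Eff_MDA) / 2.

If the co-culture architecture blocks drug penetration, the drug kills less
in the A:M spheroid than its monoculture potency predicts and PV is low.
Conventions:

- Efficacies and PVs are stored as **fractions**, rendered as percent only
  in reports.  The fractional scale is the one on which the regression
  coefficients below are meaningful.
- Negative efficacies (growth under treatment) are retained with a warning,
  never clipped; clipping would bias the regression toward zero.
- PVs are computed per replicate by default (`aggregation="replicate"`):
  with 16 drugs and 3 replicates this gives the 48 regression records of
  the screen design.  A per-drug mean alternative (`"mean"`) is available.

## The QSAR regression

The model is ordinary least squares of PV on nine physicochemical
descriptors with intercept:

    PV_hat = a0 + b1*MW + b2*logP + b3*logS + b4*HBA + b5*HBD
                + b6*PSA + b7*RotB + b8*MR + b9*Polarizability

Descriptors enter untransformed, as tabulated (logP and logS are already
logarithmic quantities; no further transform is applied).  Reported
statistics: per-coefficient t and two-tailed p, R², RMSE and the overall
F-test.  **RMSE uses the 1/n convention** (a plain root-mean-square of
residuals, no degrees-of-freedom correction); this is switchable in code by
construction (`sqrt(ssr/n)` vs statsmodels' scale) but 1/n is what the
package reports.

Feature selection is forward stepwise: from the intercept-only model, the
candidate whose entry t-test has the smallest p-value is admitted while
p < `p_enter` (default 0.05); an AIC-improvement criterion is available.
Two caveats discovered during development and worth stating plainly:

- On strongly collinear descriptor sets (see the generator below) the
  MW–MR–polarizability cluster behaves as a *suppressor set*: no member
  improves the fit much on its own, so marginal forward selection cannot
  enter the cluster at a strict `p_enter` even though the joint fit is
  excellent.  This is an inherent property of forward selection, not an
  implementation artifact.  The screen this package emulates retained all
  nine candidates; `p_enter=1.0` reproduces that configuration and is what
  the round-trip experiments use.
- With `p_enter=1.0` the stepwise refit equals the full OLS fit exactly
  (tested).

Generalization is assessed two ways, both seeded:

- an 80/20 "Pareto" split (validation size = floor(0.2 n), so 48 → 39/9);
- k-fold cross-validation (default k=5; fold sizes differ by at most one,
  so 48 → {10,10,10,9,9} with 38 or 39 training rows per fold).  Per-fold
  training/validation R²/RMSE are aggregated as unweighted fold means;
  **pooled out-of-fold metrics** (one R²/RMSE over the concatenated
  out-of-fold predictions) are reported alongside, because per-fold R² on
  9–10 observations is extremely noisy.  With k = n the procedure reduces
  to leave-one-out (verified against a direct oracle).

## Drug-likeness rules

- **Ro5**: violations are strict inequalities (MW > 500, logP > 5, HBD > 5,
  HBA > 10); a drug on a boundary does not violate.  Default
  `max_violations = 0` ("matches the rule" = no violations), with the
  common ≤ 1 reading available as config.
- **Ghose**: 160 ≤ MW ≤ 480, −0.4 ≤ logP ≤ 5.6, 40 ≤ MR ≤ 130,
  20 ≤ heavy atoms ≤ 70, all inclusive.
- **Veber**: rotatable bonds ≤ 10 and PSA ≤ 140 Å², inclusive.
- **Unweighted QED**: each of eight descriptors (MW, logP, HBA, HBD, PSA,
  RotB, aromatic rings, structural alerts) is mapped through the published
  asymmetric-double-sigmoid desirability function, normalized by the
  function maximum so d ∈ (0,1], and aggregated as the equal-weight
  geometric mean.  The desirability parameters ship as a versioned data
  file (`data/qed_params.json`); the implementation is tested to 1e-9
  against RDKit's independent equal-weight QED.  No canonical QED
  compliance cutoff exists; the default split is 0.5 and is echoed in all
  outputs as a flag.

A rule whose inputs are missing is marked "not evaluable" rather than
failing the whole profile; QED refuses to compute on a descriptor subset.

## PAMPA prediction and Caco-2 labels

Predicted PAMPA permeability uses a published four-descriptor linear model
on the log10(cm/s) scale:

    logP_PAMPA = 0.42 logP − 0.26 |pKa − pH| − 1.11 SA_HA − 1.01 SA_HD − 4.93

with pH defaulting to 7.4 (physiological; configurable and recorded in
outputs).  SA_HA / SA_HD are **fractions** of the molecular surface area
occupied by H-bond acceptor/donor atoms: with the printed coefficients
(−1.11, −1.01) only fractional inputs produce plausible logP_PAMPA
magnitudes, so the fractional convention is the default and is validated as
an invariant ([0,1]).  Drugs with logP_PAMPA < −6.14 (strict) are classed
low-permeability.  For multiprotic drugs a single pKa is used — the value
closest to the working pH.  Caco-2 classes are ingested labels
(permeable/impermeable from external ADMET sources); unmatched drugs stay
"unknown" and nothing is imputed.

## Morphometrics

From a measured area/perimeter pair: circularity = 4πA/P², sphericity
index = √circularity, equivalent diameter = 2√(A/π).  The printed shape
formula equals circularity while the screen's text takes the square root;
both quantities are therefore reported side by side rather than committing
to one reading.  From a binary mask: area is the foreground pixel count ×
pixel_size², the perimeter is the **Crofton estimate** (four directions).
The Crofton choice is deliberate: naive edge counting inflates a disk's
perimeter ~27% and even √2-weighted chain-code counting ~5%, pushing a
rasterized disk's SI to ≈0.95, while the Crofton estimate keeps it within
~0.5% of 1 for radii ≥ 20 px (tested against analytic disks and Ramanujan
ellipse perimeters).  Roundness = 4A/(π·major_axis²) with the major axis
from second-order moments.  Circularity marginally above 1 from
digitization is reported as-is with a warning, never clamped.  Multiple
mask components are reduced to the largest with a logged count.

## The synthetic study generator

No experimental descriptor/PV table is publicly deposited, so the
`synthetic` module generates a complete stand-in study; it is first-class,
tested code, and its defaults *are* the study conditions (16 drugs, 3
replicates, replicate-level PVs on a fractional scale, multiplicative
luminescence noise).  Three structural features matter:

1. **Collinearity.**  With the reference coefficients, independently
   sampled drug-plausible descriptors would put the linear predictor at
   order 1–4, far off the observed ~0–0.15 PV scale; real descriptor
   vectors are strongly collinear (MW, MR and polarizability scale
   together).  The generator samples eight descriptors within
   drug-plausible ranges and solves the linear model for polarizability so
   that a weighted share of each large term cancels, leaving
   `true PV = core + Σ (1−w_d)·coef_d·x_d` with the core drawn uniformly
   on (−0.06, 0.06).  Implied polarizabilities outside (2, 400] Å³ are
   rejected and resampled.  Polarizability values run high (~250 Å³) for
   the heaviest molecules — the price of reconciling the printed
   coefficients with the PV scale.
2. **Marginal structure.**  The cancellation weights are deliberately < 1
   for MW, logP, PSA and MR (each retains a ~0.02 marginal PV SD), because
   the real screen demonstrably had marginal descriptor–PV associations
   (its rule-compliance stratifications).  Chemically grounded couplings —
   logS = 0.5 − 0.35 logP − 0.002 MW + N(0, 0.28) (general-solubility-
   equation-inspired) and PSA = 9·HBA + 20·HBD + U(−12, 33) (TPSA-like) —
   give the full fit the screen's significance pattern: MW, logP, PSA, MR
   and polarizability come out significant in most realizations, logS,
   HBA, HBD and RotB rarely.
3. **Calibrated noise.**  Replicate PVs add Gaussian noise to the true PV.
   The default SD (0.0360) was calibrated once by bisection so that the
   expected training R² of the full nine-descriptor OLS at n = 48 is 0.69;
   at that level the expected training RMSE is ≈ 0.032 on the fractional
   PV scale.  The viability generator then inverts the efficacy/PV
   definitions: monoculture efficacies ~ U(0.3, 0.8), co-culture efficacy
   = PV + monoculture mean (feasibility-checked, marginal overshoot
   clipped with a warning), controls lognormal around a plate mean of 1e6
   counts (CV 0.10), treated signals multiplied by mean-one lognormal
   noise (CV 0.05).  At CV 0 the round trip is exact; at the default CV
   the recovered-PV bias is < 0.005 (tested over 200 replications).

Shape fixtures are rasterized disks/ellipses with exact areas and
Ramanujan-approximation perimeters as ground truth.

What the generator does **not** emulate: real drugs' discrete chemistry
(descriptors are continuous draws, not molecules), dose–response structure
(single fixed concentration by design), spatial drug-gradient effects
inside spheroids, plate-position or batch effects, and any mechanistic
link between descriptors and the monoculture efficacies.  Passing tests
therefore demonstrate correctness of the *computations* and recoverability
of a known ground truth under realistic noise — not biological validity on
real screens.

## Stand-in-based verification

Because the regression-anchored checks run on the synthetic stand-in
rather than the original data file, their tolerances come from the
stand-in's own sampling distribution, not from printed-value precision:
fitted coefficients are compared with the generating values within 4
standard errors of the fit; fit-quality metrics are compared as averages
over 50 independent screen realizations; cross-validation metrics use
3-sigma dataset-level bands measured from the construction.  Pooled
out-of-fold validation R² on a single 48-record screen varies enormously
between realizations (SD ≈ 0.17 across datasets) — a useful reminder of
how unstable small-sample CV summaries are.

## Numerical and design details

- OLS is delegated to statsmodels; correctness is cross-checked in the
  test suite against an independent normal-equations oracle (≤ 1e-8 on
  random designs up to 12 predictors / 200 rows).  Rank-deficient designs
  raise a collinearity error naming the dependent columns (detected by
  incremental rank, not by failing the solve).
- Group comparisons default to the classical equal-variance (Student)
  unpaired t-test, with Welch available.  Two groups with zero spread and
  distinct means are reported as a degenerate-variance case (|t| = ∞,
  p = 0, flag set) instead of NaN.  Three-or-more-group comparisons use
  one-way ANOVA with Bonferroni-corrected pairwise follow-ups.
- All randomness flows from explicit integer seeds; the pipeline fans one
  top-level seed into per-stage sub-seeds via `numpy.random.SeedSequence`.
  Identical config + inputs ⇒ byte-identical tables (tested).
- Text tables are written at 6 significant digits; JSON artifacts keep
  full precision.
- The `simulate` command emits a synthetic Caco-2 label table derived from
  the predicted PAMPA class purely so that the stratified comparison has
  two populated groups; real analyses must supply externally sourced
  labels.

## Limitations

- The stand-in cannot reproduce data-identical statistics of the original
  screen (exact coefficient values, the specific CV R² pair); it
  reproduces their *generating conditions* and expected magnitudes.
- Forward stepwise selection at a strict entry threshold is unreliable on
  suppressor-structured descriptor sets (above); results at
  `p_enter=0.05` should be read as "descriptors with marginal signal",
  not as the full relevant set.
- Descriptor computation from structures (RDKit path) uses QED/Crippen
  conventions, which differ from other toolkits' HBA/logP definitions;
  computed descriptors are provenance-flagged and never silently mixed
  with tabulated ones.
- pKa, logS, polarizability and surface-area fractions are never computed
  from structure (no reliable 2D route); they must be supplied.
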