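# Methods

This note documents the statistical models, the normalization, the
synthetic-data generator and the numerical choices behind `tppmelt`, and
states what the simulation-based tests do and do not demonstrate.

## Melting model

The soluble fraction of a protein after a 3-minute heat challenge at
temperature `T` (°C) is modeled as

    I(T) = I_min + (I_max − I_min) / (1 + exp[(T_m/T − 1) · s · T_m])

* `I_min`, `I_max` — lower/upper plateaus (intensity units; `I_min ≥ 0`,
  `I_max > I_min`). The three-parameter variant pins `I_min = 0`.
* `T_m` — melting point (°C), the temperature of the curve midpoint.
* `s` — slope (1/°C), negative for proteins that lose solubility on
  heating. `|s|` is approximately the logistic steepness per °C near the
  midpoint, so a 10–90% transition spans roughly `4.4/|s|` °C.

The equivalent `(a, b)` shape parameterization, `exp[−(a/T − b)]` with
`T_m = a/b` and `s = −b²/a`, is provided and property-tested against the
`(T_m, s)` form.

All temperatures are Celsius. The `T_m/T` ratio is therefore a
Celsius-scale ratio; this matches melting points reported in °C and fits
performed on a °C grid. Using Kelvin inside the exponent would change the
meaning (not just the value) of `s`; the Celsius convention is fixed
throughout and round-trips exactly between the two parameterizations.

### Fitting

Unweighted nonlinear least squares (`scipy.optimize.curve_fit` with an
analytic Jacobian), multi-start over a small grid: `T_m` starts at the
median grid temperature and the half-range crossing of the data; slope
starts −0.5 and −0.05; plateau starts from the data extremes. Bounds:
`T_m ∈ [T_min − 10, T_max + 10]` °C, `I_min ∈ [0, ∞)`, `s ∈ [−10, 10]`;
parameter tolerance 1e−8. A four-parameter fit that fails, pins `T_m` to a
search bound, or inverts the plateaus falls back to the three-parameter
model. The scale factor of data onto a frozen curve has the closed-form
least-squares solution `sf = Σ(y·m)/Σ(m²)`.

## Three-step normalization (temperature-range mode)

1. **Within each temperature.** The six samples of one heat-challenge
   temperature (2 arms × 3 replicates) are aligned to a reference sample —
   the one with the most positive median log2 fold changes against the
   others (ties break to the lowest column index) — by multiplying each
   other sample by `c = 2^median(log2(reference/sample))`. The fold-change
   orientation is reference/sample: this is the only orientation under
   which multiplying by `c` drives the median log2 fold change to zero.
   The step assumes most proteins are unaffected by treatment; cohorts
   violating this (e.g. a simulation where *every* protein is shifted)
   will see real effects absorbed into the constants.
   *Idempotence:* with the reference retained, re-applying the step is an
   exact no-op; a fresh reference selection is idempotent only up to the
   non-transitivity of median fold changes (≈0.04 log2 units at 30
   proteins, shrinking with cohort size). `normalize_tr_step1` therefore
   accepts fixed references.
2. **Between temperatures.** For each temperature, the mean of the 36
   pairwise median log2 fold changes of its six samples against the six
   lowest-temperature samples gives a summary intensity `I(T)` (for the
   lowest temperature itself the pairwise comparisons cancel, so
   `I(T_low) = 1` identically). The melting sigmoid is fitted to the
   `(T, I(T))` points and every sample of a temperature group is
   multiplied by `c(T) = I_fit(T)/I(T)`. Within-temperature ratios are
   untouched. Note this step is exactly neutral only when the summary
   points lie on one sigmoid (e.g. homogeneous melting curves); with
   heterogeneous cohorts the residual `c(T)` structure adds a small shared
   distortion (~0.1–0.4 °C on fitted melting points at realistic
   heterogeneity), which is inherent to the global-curve scheme.
3. **Per-protein labeling-set leveling.** Each protein's labeling sets are
   first leveled by their maxima, then three rounds of (combined 4-param
   fit with 3-param fallback) → (closed-form per-set scale factor, divided
   out) bring the sets onto a common curve; a round whose scale factors
   are all within 1e−6 of 1 stops early. Within-set ratios are preserved
   exactly in real arithmetic (to ~1 ulp in floating point, since whole
   sets are multiplied by shared constants).

**Quality filter.** A protein is analyzed only if quantified in ≥ 80% of
the channels of *every* labeling set (configurable). This is this
package's own surrogate for upstream data-quality filtering; excluded
proteins are reported with a reason, never dropped silently.

## Differential analysis

Per protein:

* **Per-temperature tests** — mean of per-replicate
  log2(compound/vehicle) within matched (temperature, replicate), with a
  two-sided one-sample t-test against zero (n = replicate pairs).
  Zero-variance ratios are degenerate: p = 1 for an all-zero effect, the
  minimal representable p (flagged) otherwise.
* **ΔT_m** — each arm of each replicate is fitted separately; the mean
  per-replicate difference is tested with a one-sample t-test. Replicate
  fits are deliberately not pooled so a dispersion estimate exists.
* **Abundance** — the same ratio test restricted to the lowest
  temperature, where melting has not begun.
* **Distance score** — sign(mean log2 ratio over the significant
  temperatures, at the uncorrected per-temperature α = 0.05) ×
  √(Σ squared log2 ratios over those temperatures); zero with no
  significant temperature. The collation ratio is 2^(mean log2 ratio over
  the significant temperatures). This scoring (and the protein-level flag
  below) is this package's own collation of the paired design and is the
  single place to substitute an alternative definition.
* **Protein-level significance** — Fisher combination of the
  per-temperature p-values, Benjamini–Hochberg adjusted across proteins,
  flagged at α = 0.05. Classification is by the dominant effect: stability
  and abundance each count when their own p < α; when both do, the larger
  standardized effect (|t|) is primary.

Scale invariance (global rescaling changes nothing) and arm-swap
antisymmetry (ΔT_m, ratios and score negate) hold by construction and are
property-tested.

**CETSA path.** Single-protein immunoblot series (2 arms × 3 replicates ×
temperature grid) are normalized by the fitted `I_max` of a
three-parameter fit per series — making the analysis invariant to
arbitrary positive rescaling of any series, as densitometry units are
arbitrary — then run through the same ΔT_m and per-temperature machinery.

## Dose-response analysis (concentration-range mode)

Normalization: within each labeling set, samples are aligned (median log2
fold change) to the set's vehicle (0 nM) channel; each protein is then
expressed relative to its mean vehicle-channel intensity per assay
temperature.

The response is the standard four-parameter log-logistic curve in log10
dose with parameters pEC50, Hill slope `H` and two plateaus. The
parameterization has an exact symmetry (negate `H`, swap plateaus);
fitted parameters are canonicalized to `H > 0` so the response direction
is `sign(r_high − r_low)`. The vehicle point enters only the
normalization, never the fit (it has no defensible log-dose coordinate).
Fits are best-of-16 multi-starts over pEC50 ∈ {9.5, 8.2, 6.8, 5.5} ×
H ∈ {−3, −0.33, 0.33, 3}; pEC50 is bounded to [4, 12] and fits landing on
that bound are flagged non-responders. Quality is pseudo-R² = 1 − RSS/TSS
(0 by definition for constant data).

Classification: responders need pseudo-R² ≥ 0.8 at 50 °C. Mechanism =
*stability* when the 50 − 37 °C pseudo-R² difference is ≥ 0.4 (config)
and the 37 °C fit is below threshold; *abundance* when both temperatures
respond above threshold in the same direction; *mixed* otherwise. The 0.4
difference threshold is a design choice of this package.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* temperature-range design: 10 temperatures 36.5–67.0 °C split over two
  TMT 10plex sets per replicate (paired arms per temperature), 3
  replicates → 60 samples; concentration-range design: 0 plus a 9-step
  fourfold dilution to 6400 nM, at 50 °C and 37 °C, 3 replicates → 60
  samples;
* per-protein vehicle curves: baseline abundance log-uniform over three
  orders of magnitude (1e5–1e8), `I_max = 1` (relative), `I_min` ~
  U[0, 0.15], `T_m` ~ U[42, 60] °C (informative on the grid), slope ~
  U[−0.75, −0.3] — transition widths of ~6–15 °C, typical of proteome
  melting curves;
* effects: +2.0 °C melting-point shift for stabilized proteins (the scale
  of genuine small-molecule target engagement; −2.0 °C for destabilized)
  and ±1 log2 abundance shifts applied at all temperatures;
* noise: mean-one log-normal multiplicative noise per intensity (default
  CV 0.1 — the replicate variability of well-behaved TMT reporter data; no
  published value exists for this design, so it is exposed in the noise
  model), per-sample log2 scale errors shared across proteins (default SD
  0.1; exactly what step 1 must remove), and Bernoulli dropout;
* dose-response truth: at 50 °C a (de)stabilized protein interpolates
  log-logistically (default pEC50 8.58, H = 1) between its vehicle
  survival and its shifted-curve survival, flat at 37 °C;
  abundance-affected proteins carry the same dose trend at both
  temperatures.

Reproducibility: one master seed; every protein draws from a substream
derived from (seed, protein index), so enlarging a cohort never perturbs
earlier proteins.

**What the simulations do not emulate:** peptide-level quantification and
roll-up, TMT isotopic impurity and co-isolation interference,
intensity-dependent missingness, correlated (batch) noise, and melting
curves that deviate from the two-state sigmoid. Passing recovery and
calibration tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to real-data artifacts.

## Measured performance under the default conditions

Established by direct repeated simulation (the same code paths the test
suite runs):

* Noise-free, homogeneous-curve cohorts: the full pipeline returns
  melting parameters and ΔT_m equal to truth to ≈1e−6.
* cv 0.1, 3 replicates: a single 10-point curve fit has a `T_m` SD of
  0.3–1.4 °C across the realistic parameter range — so per-protein ΔT_m
  estimates carry ~0.4–0.8 °C standard error, while a 10-protein cohort
  mean recovers a +2.0 °C shift within ±0.5 °C in ~100% of runs, and the
  pooled 60-point combined fits of the normalization achieve a median
  `T_m` error below 0.5 °C over hundreds of proteins.
* cv 0.05 single fits land within 0.3 °C of the true `T_m` in roughly 70%
  of trials; this oracle-measured rate (not a higher aspiration) is what
  the unit test asserts, with margin for seed variation.
* Null cohorts (no effects, cv 0.1): per-temperature p-values are uniform
  (they are exact t-tests under the log-normal noise model) and the
  BH-adjusted protein-level flag keeps the false-positive fraction at or
  below the nominal level. The calibration simulations set the per-sample
  scale errors to zero because step-1 normalization removes exactly that
  component in practice; a separate test verifies that removal.
* Dose-response fits on the standard grid at cv 0.05 recover pEC50 8.58
  with a median absolute error of ~0.05.

## Problem sizes and runtime

The test suite and the acceptance script use cohorts of 200–1000 simulated
proteins, 200-run recovery studies and 200-fit dose-response studies —
sizes at which medians, rates and KS tests are stable but a full run
completes in minutes on one CPU. Larger cohorts change none of the
qualitative conclusions.

## Known limitations

* The global-curve step (step 2) is exactly neutral only for homogeneous
  melting behavior; its residual distortion is shared by both arms, so
  ΔT_m is far less affected than absolute `T_m`.
* The distance score and protein-level flag are this package's own
  collation scheme; effect classifications near the per-temperature α are
  sensitive to that choice.
* The abundance/stability split in CCR mode inherits the 0.8 / 0.4
  pseudo-R² thresholds; proteins with weak melting amplitude at 50 °C are
  genuinely hard to classify at realistic noise and may be reported as
  non-responders.
* No robust/outlier-resistant fitting; a single aberrant channel can move
  a per-replicate fit.
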