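# Methods

## The calibration problem

A diffuse-reflectance NIR spectrum of powdered plant material is, to a
good approximation, a linear mixture of the absorbance signatures of its
constituents, distorted by per-sample scatter (a multiplicative slope
and an additive offset from particle-size and packing variation), a
smooth baseline, and detector noise. The quantity of interest is the
total content of two isomeric triterpenoid acids (oleanolic + ursolic,
mg/g), assayed by HPLC on a reference set. The package fits and
evaluates calibrations that map spectra to that total.

Two properties of this system shape everything downstream:

1. **The isomers are spectrally near-degenerate.** Their C–H/O–H
   combination and overtone bands share centers to within ~10 cm⁻¹.
   Regressing either acid alone is ill-posed; their *sum* is well
   determined. The package therefore treats the total as the default
   modeling target (`oa` and `ua` remain selectable).
2. **Scatter dominates the raw cross-sample variance**, which is why MSC
   (or VN) is screened first and why MSC's reference spectrum must be
   fitted on the calibration set only and frozen for all later data.

## Pipeline and its state

Order of operations: restrict to the working window (9,000–4,000 cm⁻¹ by
default, where the informative features sit) → pretreatment chain →
interval division / band selection → mean-centered NIPALS PLS1 →
optionally a small neural net on the PLS scores. The only data-dependent
pretreatment state is the MSC reference; `apply_pretreatments` returns a
frozen `FittedPretreatment` whose SHA-1 fingerprint is stamped on
transformed spectra, and `CalibratedModel.predict` refuses spectra
carrying a foreign fingerprint. Standalone `loocv_curve` refits the
entire chain (MSC reference, centering, PLS) on each fold's n−1 samples;
inside the SiPLS screening loop the chain is fitted once on the full
calibration set before interval division — the workflow instrument
software uses — and cross-validation within each combination refits
centering and PLS per fold.

## Numerical choices

- **NIPALS rather than SIMPLS**: identical predictions for a single
  response, and the factor-by-factor "rank" vocabulary matches field
  usage. Deflation stops early (with a warning) when no covariance
  remains; per-rank coefficients come from W(PᵀW)⁻¹q with a triangular
  solve.
- **Mean centering only, no autoscaling** — absorbance columns share
  units.
- **R² is 100·(1 − SSE/SST)** with SST about the mean of the observed
  values (not a squared correlation); it can be negative.
- **RPD uses the calibration-set SD** by definition; the caller may pass
  the evaluated set's SD instead, since published tables are not always
  consistent about the convention.
- **Savitzky–Golay**: polynomial order defaults to 2 (the common
  instrument-software convention when only a point count is quoted);
  derivatives are SG derivatives with respect to wavenumber, scaled by
  (−1/step)^d because the grid is stored in descending acquisition
  order. Edges use shrink-window polynomial refits — no reflection or
  padding fabricates data outside the measured range, and polynomial
  reproduction stays exact at the boundaries.
- **Rank selection** minimizes RMSECV(a) + RMSEP(a), ties to the smaller
  rank. Within SiPLS, rank is RMSECV-minimal and the winning combination
  is RMSECV-primary (validation results are reported, not optimized, to
  limit selection bias); ties prefer fewer intervals, then lower rank.
- **Interval division** is equal-width by default; instruments'
  automatic divisions need not be equal-width, so explicit edges are
  accepted. Interval membership is half-open (lo, hi] with both outer
  edges kept, so adjacent intervals never share a column and the union
  is exactly the window.
- **BP-ANN**: min-max scaling of inputs and target to [−1, 1] fitted on
  calibration data (validation values extrapolate beyond [−1, 1] —
  deliberately unclipped); Nguyen–Widrow-style seeded initialization;
  Møller's scaled conjugate gradient with goal MSE 0.001 *on scaled
  targets*, at most 1,000 epochs; optional restarts keep the best final
  calibration loss. The quoted fixed learning rate 0.1 is inert under
  SCG (which has no step-size parameter); it is retained for the plain
  gradient-descent trainer (`train_gd`) that represents the classic BP
  learning rule. Full-CV is leave-one-out, with per-fold re-seeded
  initialization and per-fold refitted scalers; RMSEP_c comes from the
  pooled held-out predictions, not from refit-on-all residuals.
- **Hidden-node screening** picks the smallest h whose Full-CV and
  external-validation RMSEPs both lie within 10% of the respective
  minima (parsimony among near-optimal models); if no h is near both, the
  sum decides.

## The synthetic generator

`simulate_dataset` draws concentrations from truncated normals matched
to the study design (calibration statistics: OA mean 7.7, SD 2.6 on
[1.9, 13.4] mg/g; UA mean 1.5, SD 1.0 on [0.2, 5.0] mg/g; 122 samples,
of which 90 model and 32 test), synthesizes each component as a sum of
Gaussian bands at the assigned wavenumbers (5,177 / 5,784 / 7,230 /
4,712 / 4,400 / 4,329 / 4,260 cm⁻¹, UA shifted ~10 cm⁻¹), adds three
broad matrix interferents, a fixed smooth baseline, per-sample lognormal
slope and normal offset, and i.i.d. noise per replicate; three
replicates are averaged. Identical seeds give bit-identical output, and
the latent draws are returned for recovery tests.

Defaults were fixed once: scatter slope sigma 0.08 and offset sigma
0.01 AU are typical of repacked powder cells; noise SD 0.008 AU per
replicate was calibrated so that the default pipeline lands where a
usable herbal-material calibration lands (validation RPD ≈ 3.5–4.5,
R² ≈ 92–96%) — it is a statement about the simulated study conditions,
not about any particular spectrometer.

**Nonlinearity.** `gamma > 0` saturates the spectral response of the
isomer pair with the *total* analyte load: the analytes' effective
concentrations are scaled by 1 − γ·T/(2·T_max). The readable sum
coordinate in spectral space is then a curved function g(T) of the
assayed total, so no linear functional of the spectra recovers T
exactly, while a smooth nonlinear reader of the PLS scores can invert
g — the regime in which a score-fed neural net genuinely outperforms
linear PLS. This mechanism was chosen deliberately: an elementwise
polynomial distortion of a K-component linear mixture (e.g. adding
γ·clean²) only adds O(K²) extra signature directions to the spectra,
and with hundreds of channels a linear functional that annihilates them
while reading the total always exists — the prediction problem stays
exactly linear and a nonlinear model can never help, as a
quadratic-oracle experiment on the scores confirms. γ = 0.5 (12%
compression at the mean load, 20% at maximum) defines the package's
"mild nonlinearity" condition.

**What the generator does not emulate**: wavelength-dependent pathlength
effects, band shifts/shape changes with temperature or matrix, detector
nonlinearity, water-activity coupling, or correlated (pink) noise.
Passing tests therefore demonstrate correctness of the estimator
machinery and sound behavior under the assumed noise model — not
instrument-transferable accuracy on real material.

## Problem sizes used in tests and the acceptance script

Unit and property tests run on reduced grids (steps of 16–200 cm⁻¹) and
sample counts (5–60) chosen so each check isolates one property; the
acceptance script runs the full default conditions (1,063-point grid,
122 samples, all 31 interval combinations, all six hidden-node
candidates) plus ten seeded replicates of the nonlinear comparison at
the final model configuration (MSC, rank 14, h = 2, 3 restarts).

## Known limitations

- The SiPLS screening freezes pretreatment on the calibration set; a
  fully nested screen (chain refitted inside every fold of every
  combination) would be slower and slightly more conservative.
- Whether a published RPD divides by the calibration or evaluated set's
  SD is not always recoverable; both conventions are exposed.
- The BP-ANN reports depend on initialization seeds; Full-CV derives
  per-fold seeds deterministically, so results are reproducible but not
  seed-free.
- `select_rank` needs an external-validation curve; with very small
  validation sets its RMSEP term is noisy and the RMSECV-primary SiPLS
  rule is the more stable guide.
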