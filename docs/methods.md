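# Methods

## Signal model and simulation

Every synthetic voxel follows the two-compartment bi-tensor model

    S(b, g) = S0 · [ (1 − f) · exp(−b gᵀ D g) + f · exp(−b · d_iso) ]

with a symmetric positive-semidefinite tissue tensor D (mm²/s), a free-water
volume fraction f ∈ [0, 1], and the free-water diffusivity fixed at
d_iso = 3×10⁻³ mm²/s exactly. Noise, when requested, is Rician: Gaussian
noise of width σ = S0/SNR on two quadrature channels, magnitude taken. SNR
is defined on the b0 signal. All randomness flows through
`numpy.random.default_rng` seeds supplied by the caller; identical
configuration and seed give bit-identical outputs.

Gradient schemes mirror a two-run clinical acquisition: per series, b0
volume(s) (one in the first series, two in the second) plus `n_dirs_half`
directions spread over a half sphere and their antipodes, all at one
b-value (default 21 + 21 at b = 1000 s/mm², 87 volumes over two series).
The half-sphere layout starts from a golden-section spiral and is polished
by electrostatic repulsion that includes antipodal interactions, with a
fixed internal seed — the scheme is a deterministic function of its
arguments. Fewer than 6 directions is refused: the tensor has six degrees
of freedom.

`tensor_from_scalars(fa, md)` inverts the prolate eigenvalue triple
(λ1, λ⊥, λ⊥) in closed form from FA = |λ1 − λ⊥| / √(λ1² + 2λ⊥²):
λ1 − λ⊥ = FA·MD·√(3 / (1 − 2FA²/3)). This is how planted tensors matching
any target FA/MD are built.

## Conventional tensor fit

`DiffusionTensorModel` solves the log-linearized system
ln S = ln S0 − b gᵀDg by ordinary least squares followed by one weighted
refinement pass with weights equal to the squared predicted signal — the
standard WLS estimator. S0 is a joint unknown of the linear system, not the
b0 mean, so multiple b0 volumes are treated consistently. Negative
eigenvalues are clamped to zero and the voxel flagged rather than rejected,
preserving map completeness; a fully clamped (all-zero) voxel reports FA 0
with its flag set, so pure-noise voxels cannot poison a map. FA uses
√(3/2)·‖λ − MD‖/‖λ‖; RD is the mean of the two smaller eigenvalues; AD the
largest. On noise-free data the inversion is exact (relative error ~1e−9 in
the tests), so the choice among OLS/WLS/NLLS is immaterial for the recovery
contracts; WLS was chosen as deterministic and iteration-free.

## Free-water elimination fit

`FreeWaterModel` fits (f, D) per voxel by bounded nonlinear least squares
(scipy trust-region-reflective) on the attenuation signal, with:

- D parameterized through its lower-triangular Cholesky factor, so positive
  semidefiniteness is structural, working in units of 10⁻³ mm²/s to keep
  the optimizer variables O(1);
- f bounded to [0, 1]. The trust-region solver handles active bounds
  without gradient pathologies, and an interior clamp would demonstrably
  bias the f = 0 voxel (the tissue tensor must absorb a forced water
  compartment); initialization is clamped to [0.01, 0.99];
- initialization: f from linear interpolation of the conventional MD
  between a tissue prior of 0.6×10⁻³ mm²/s (typical healthy white matter;
  initialization only, never a constraint) and d_iso, and D from the
  conventional tensor with the isotropic share removed,
  (D_conv − f·d_iso·I)/(1 − f), projected to SPD;
- stopping at relative cost change < 1e−10 or 500 residual evaluations;
  non-convergence flags the voxel, it never raises;
- voxels whose fitted tissue FA falls below 0.05 are flagged degenerate:
  with isotropic tissue the single-shell signal is direction-independent
  and (f, D) trade off exactly.

An optional outer loop Gaussian-smooths the fraction map (σ = 1 voxel)
over a mask between refits. It is off by default so the default estimator
stays strictly per-voxel and its contracts exactly testable.

### Identifiability: what noise does to single-shell FWE

On noise-free single-shell data with anisotropic tissue the model is
identifiable and the fit recovers planted parameters to ~1e−6 (the
direction-dependence of the tissue term separates it from the flat
free-water floor). Under noise this separation collapses: at SNR 20 with 87
volumes the Cramér–Rao bound for per-voxel f is far wider than [0, 1] — the
f/tissue-diffusivity trade-off is a near-flat valley, and per-voxel
estimates at a planted f of 0.141 scatter with RMSE ≈ 0.25 whatever the
optimizer. This is the well-documented reason practical single-shell FWE
relies on strong spatial regularization, and why multi-shell acquisitions
are preferred for free-water mapping. Consequently the package's tested
noisy contracts are the attainable ones — bounds respected, flags
populated, Rician noise floor reproduced — while quantitative recovery
contracts are stated and tested noise-free. Passing tests therefore
demonstrate correctness of the estimator, not that per-voxel single-shell
free-water maps at clinical SNR are quantitatively reliable; they are not,
and results on real data of that kind inherit the regularization choices
made to stabilize them.

## Phantoms

`make_phantom` builds, on a grid of at most 64³ voxels (default 24×24×16,
2 mm isotropic): an intracranial box, a white-matter slab inside it, two
tube-shaped bundles (default radius 1.6 voxels) inside the slab, and a
lesion blob that overlaps the bundle by a requested fraction (grown along
the left bundle, padded with nearby slab voxels). Bundle voxels carry an
axially symmetric tensor along the tube (default FA 0.567, MD 0.755×10⁻³
mm²/s) and free-water fraction 0.141; slab voxels a more isotropic tensor
(FA 0.35, MD 0.80×10⁻³) with f 0.25; lesion voxels get +0.2 free water;
the non-slab rim behaves like cerebrospinal fluid (f 0.95). These defaults
are healthy-elderly cingulum values; the bundle voxel count is a free
parameter chosen for desk-scale runtime, as no reference voxel count exists
for an extracted cingulum. Ground truth (tensors, fractions, S0) travels
with the object and is written to a sidecar CSV next to the NIfTI outputs.

What the phantom does **not** emulate: curved anatomy, crossing fibers,
eddy currents, motion, susceptibility distortion, multi-shell schemes,
spatially correlated noise, or realistic lesion texture. Tests passing on
these phantoms validate the estimators and the pipeline plumbing, not
tractography or segmentation performance on real scans.

## Longitudinal trajectories and slopes

Fluency counts follow score(t) = (μ0 + b0ᵢ) + (μ1 + b1ᵢ + γ·covᵢ)·t + ε
with independent Gaussian random effects and residuals; the 30 s and 60 s
counts add nonnegative increments to the 15 s count, because the three
scores are cumulative word counts of one trial — so IST15 ≤ IST30 ≤ IST60
holds at every visit by construction. Defaults: visits at 0, 2, 4, 7, 10,
12 years; mean intercept 30 words; mean slope −0.489 words/year; SD 2
(intercept), 0.15 (slope), 1 (residual). γ plants a diffusion–slope link
for positive-control runs.

`IstSlopeModel` fits score ~ time with correlated random intercept and
slope per subject by REML (statsmodels MixedLM; deterministic optimizer, no
seed dependence). The subject slope is the fixed slope plus the BLUP of the
subject's random slope; two-stage per-subject OLS slopes are always carried
alongside as a cross-check. A near-singular joint random-effect covariance
triggers a flagged refit with independent random effects. Exactly linear
(zero-residual) trajectories make REML singular; they are detected and
returned as the per-subject OLS solution, which is exact there. Missing
visits are allowed; a subject with no usable rows is dropped and logged.

## Association layer

- Spearman rank correlation with average ranks for ties; two-sided p by
  exhaustive enumeration of all n! orderings for n ≤ 7, t-approximation
  above (full enumeration beyond 7 costs minutes per call for no practical
  gain in accuracy).
- Mann-Whitney U: exact null distribution for untied samples up to total
  n = 20, otherwise the tie-corrected continuity-corrected normal
  approximation (scipy).
- Paired t on corrected-vs-conventional measures; identical vectors return
  t = 0, p = 1 (null differences carry no evidence), while a constant
  nonzero shift — zero variance with nonzero mean — is refused as
  degenerate.
- Adjusted regressions z-score the outcome and the predictors of interest
  and enter covariates raw, so the reported coefficients are standardized
  β "adjusted for" the covariates; default covariates are age and bundle
  volume as % of intracranial volume (the volumetric table's convention;
  configurable). R² comes from the full model. Joint models (free water +
  corrected MD) and lesion-adjusted variants add columns to the same
  design.
- Benjamini–Hochberg step-up at q = 0.05, applied per results family: one
  family per results table (the conventional block and the corrected block
  of the measure × score grid), matching how such results are presented;
  the grouping is configurable.
- All tests two-sided.

The null calibration of this layer is checked at the cohort level: 600
simulated null cohorts of 68 subjects give a family-wise BH rejection rate
of ~4–5%, within the 7% acceptance margin; a planted standardized β of
−0.4 on corrected MD is recovered with >70% power at FDR 0.05.

## Pipeline

`run_pipeline` chains generate → fit → aggregate → slopes → associate from
one `PipelineConfig` (YAML round-trip, seeds recorded in a manifest with
per-stage wall times). Stages cache on a hash of their config section and
skip when unchanged, so association reruns are bit-identical without
re-fitting voxels. Per-subject tissue state (bundle FA, MD, free-water
fraction) is drawn around the cohort means so tract measures vary across
subjects; tiny cohorts (< 10 subjects) fall back from the mixed model to
per-subject OLS slopes, and covariates are trimmed when n cannot support
them. Tract means are unweighted over mask voxels — mask-based tractometry
is the closest testable surrogate for streamline-based aggregation, which
would require a tractography stage. The lesion log-volume uses
ln(WMH/WM + ε) with ε = one voxel's share of the WM volume, keeping
lesion-free subjects finite; natural log, since the base only rescales
regression coefficients.

## Numerical and degenerate-input choices

- f reported in [0, 1]; optimizer bounds [0, 1] with Cholesky diagonal
  floored at 1e−4 internal units (1e−7 mm²/s) so the tissue tensor never
  collapses to an exactly singular factor.
- Tensor eigenvalue clamping at zero with flags, never rejection.
- Spearman on constant input, regression on constant columns, empty masks,
  zero white-matter volume, p-values outside [0, 1]: all refused with
  specific errors naming the offending input.
- Exclusion screening is sequential: a subject counts at the first stage
  that excludes them, so the per-stage counts sum with the included count
  to the screened total (the printed 239 → 68 funnel sums only under this
  attribution).

## Problem sizes

Defaults used by the test suite and the acceptance script: 87-volume
schemes; single voxels or 500-voxel batches for recovery and direction
contracts; phantoms of 16³–24³ with ~60–200 bundle voxels; cohorts of 68
(the study size) for association checks, 600 null and 200 positive-control
replicates at the cohort level; 2000 subjects for the mixed-model recovery
and 50 replicates of 68 for its small-sample bias. These sizes make every
contract testable on a desk machine in minutes.
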