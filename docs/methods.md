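# Methods

This note documents the models implemented in `scnpls`, the choices made
where the design was genuinely open, and what the synthetic validation does
and does not establish.

## Two-block PLS correlation

Given subject-aligned blocks `X (n × p)` and `Y (n × q)`, both blocks are
column mean-centred (and unit-variance scaled under `scaling='correlation'`)
and the cross-block matrix `R = Yᶜᵀ Xᶜ / (n − 1)` is decomposed by SVD,
`R = U S Vᵀ`.  Each latent variable (LV) pairs a left salience (column of
`V`, unit norm), a right salience (column of `U`) and a singular value;
subject scores are `Xᶜ V` and `Yᶜ U`; variance explained by LV *l* is
`s_l² / Σ s²`, which sums to one by construction.

Design choices:

* **What is decomposed.**  Seed PLS decomposes the seed × voxel cross-block
  rather than the participant × voxel data matrix itself.  For a single
  seed the two readings coincide up to scale — LV1's salience is then the
  normalized seed–voxel covariance map — and the cross-block form is the
  standard seed-PLS formulation and generalizes cleanly to 2-seed blocks.
  Both behaviours are reachable through the same engine (pass the blocks
  you want).
* **Scaling.**  Covariance scaling (centring only) for seed PLS — GM
  probabilities share units and their variance structure is meaningful;
  correlation scaling for behavioural PLS — the 17 tests live on
  heterogeneous scales.  Both are configurable.
* **Sign convention.**  SVD signs are arbitrary; each LV is oriented so the
  right-salience element of largest magnitude is positive.  Saliences are
  therefore interpretable only relative to each other, which is also why
  bootstrap replicates are sign-aligned (orthogonal Procrustes alignment is
  available; with one dominant LV the two coincide).
* **SCN granularity.**  Subject-level SCN scores come from 12 single-seed
  models (one score per seed); per-network salience/BSR maps come from the
  2-seed block of each network.

## Permutation inference

LV significance: subject rows of the behavioural block are randomly
reordered `n_perm` times (single stream, the same permutations reused for
every LV and for the latent-correlation null), the model is refit, and
`p_l = (1 + #{s_l^perm ≥ s_l}) / (n_perm + 1)`.  Each LV is compared on its
own singular value, without Procrustes correction of the null.

**Permutation under confound residualization.**  Both blocks of the
behavioural model are residuals against one shared nuisance design.
Shuffling residual rows directly is anti-conservative: all residual columns
live in the same `(n − k − 1)`-dimensional subspace, row permutation
destroys that shared structure, and the permuted singular values run
systematically small (measured: 11% rejections at α = 0.05 over 200
decoupled longitudinal cohorts).  The engine therefore accepts the nuisance
design and, inside every permutation, permutes the *raw* behavioural rows
and re-residualizes them against the unpermuted design (a Freedman–Lane
scheme restricted to nuisance-only models); the bootstrap likewise refits
the nuisance model within every resample.  Measured null rejection with the
corrected scheme: 7.5% (200 cohorts), inside the binomial 95% band.
Because residualization is idempotent, already-residualized inputs remain
valid; only the null changes.

Defaults for desk-scale runs are 200 permutations / 100 bootstrap resamples
(the p-value floor `1/(n_perm+1)` ≈ 0.005 is granular enough for
calibration studies); `full_scale: true` raises them to 5000 / 1000, which
only refines p-value granularity.

## Bootstrap stability

Subjects are resampled with replacement (paired rows), the model refit and
aligned, and each salience element's bootstrap ratio is its original value
divided by the standard deviation of its replicates — a Z-like statistic;
|BSR| ≥ 2 is the conventional contribution criterion.  A zero bootstrap SE
(exactly reproducible salience) yields a signed infinite sentinel, counted
and surfaced in reports rather than silently dropped.  Loading CIs are
percentile 2.5–97.5% intervals of `corr(feature, opposite-block score)`
across replicates.

## Missing-data imputation

Missing battery cells (a few percent, assumed MCAR) are completed
iteratively: start from observed column means; each iteration z-scores
every column of the current completed matrix (auto-scaling statistics are
recomputed as imputations move), rebuilds the missing cells from a
rank-`k` SVD reconstruction, and stops when the largest change of any
imputed cell in scaled units falls below `tol`.  Defaults: `k = 2`,
`tol = 1e-6`, `max_iter = 500`.  Recomputing the scaling each iteration
matters: with statistics frozen at observed cells a rank-1 table with one
deleted cell converges to a biased completion, whereas completed-matrix
statistics make exact rank-1 recovery a fixed point.  Non-convergence is a
flagged warning, never silent; convergence can be slow (hundreds of
iterations) when the k-th and (k+1)-th spectral gaps are small, which is
harmless in practice because the reconstruction has stabilized to well
below test-score resolution.  Each timepoint's battery is imputed
separately; change scores are differences of the completed tables,
residualized afterwards with scan interval included.

## Confound model

Residualization is ordinary least squares per column against an intercept
plus age, sex, handedness, log-transformed infarct volume (log(V + 1 mm³)
to keep zero volumes finite) and total intracranial volume; the scan
interval is appended for longitudinal change scores.  The column set is
fully configurable, which is how the global-atrophy and no-infarct-volume
sensitivity variants are expressed.  Rank-deficient designs fall back to
minimum-norm least squares with an explicit collinearity warning.

## Geometry

Masks are defined on the group-mean GM image (mean ≥ 0.45), guaranteeing
one common voxel set across subjects, which covariance analysis requires;
per-subject thresholding (mask intersection) is exposed as an option.
Sphere membership uses the voxel-centre-to-seed Euclidean distance in mm
through the affine, with a closed boundary — exactly testable against
brute-force lattice scans (257 voxels at r = 4 mm on a 1-mm grid; 7 on a
4-mm grid).  Voxel order is C-order over the grid; mm ↔ voxel conversion
happens only through the affine; voxel indices are 0-based.

## Synthetic cohort generator

The generator emulates the *output* of a longitudinal VBM preprocessing
chain — it makes no attempt at anatomy, segmentation or registration.

* **Grid.**  24 × 28 × 24 voxels at 4-mm spacing (a desk-scale stand-in
  for 1-mm MNI), with an ellipsoidal brain support; all mm-based logic
  (4-mm seed spheres, 8-mm FWHM smoothing) honours the affine, so unit
  conversions are genuinely exercised.  Seed coordinates scale with the
  grid extents so smaller test grids remain valid.
* **Networks.**  Six networks, two seeds each; loading maps are truncated
  Gaussian bumps (σ = 6 mm) peaking at the seed spheres with weaker
  satellite foci, truncated so off-network loadings are exactly zero and
  every planted voxel carries substantial loading.
* **GM model.**  `GM_i(v) = baseline(v) + Σ_k L_k(v) f_ik − age term +
  smoothed noise`, clipped to [0, 1].  Factors
  `f_ik = √a·u_i + √(1−a)·e_ik` share an integrity latent `u`
  (`a = 0.8`), making the 12 seeds strongly co-vary — the empirical
  near-rank-1 behaviour of SCN scores follows.  Loading amplitude 0.08 GM
  per factor SD and voxel noise SD 0.015 (post-smoothing) put seed means
  at r ≈ 0.9 with their planted factors.
* **Decline.**  Per-network rates `~ N(1.0, 0.5)` truncated at zero,
  sharing a decline latent `v`, multiplied by the per-subject scan
  interval in years — so the scan-interval confound is genuinely
  informative.
* **Cognition.**  A cognition latent `w = ρ u + √(1−ρ²) η` drives the
  battery, so ρ *is* the model's attainable brain–behaviour latent
  correlation; six tests couple strongly (weight 1), eight weakly (0.4),
  three not at all; timed tests are generated "higher worse" to exercise
  direction metadata.  Test noise SD 0.5 gives realistic inter-test
  correlations.  Longitudinal coupling mirrors this through
  `g = ρ_change·v + …`.  Setting the coupling multipliers to zero yields
  exact null cohorts.
* **Demographics.**  Age ~ N(67.41, 12.13), scan interval ~ N(276.92,
  26.14) days, infarct volumes log-normal moment-matched to mean 5786.62
  / SD 9316.65 mm³ but clipped at 20 000 mm³ — the desk-scale brain cannot
  host the distribution's extreme tail (a 33-mm-radius sphere) away from
  the seed exclusion zone; the clip affects ~5% of draws and moves the
  sample mean by ~13%.  Lesions are spheres placed outside all seed
  spheres, locally depressing GM; missingness is MCAR at 4% per timepoint.

### What passing tests show — and what they do not

The synthetic cohorts validate the *estimator chain*: that the
decomposition, inference, imputation and confound handling recover planted
structure at realistic n and noise, with calibrated nulls.  They do not
show that real post-stroke GM covariance is rank-1, that real batteries
follow a one-factor coupling, or that real lesions spare seed regions; nor
do they exercise registration error, scanner drift, or non-MCAR
missingness (MAR hooks exist but default off).

### In-sample latent r is optimistic

The LV1 latent correlation reported by PLSC is computed in-sample: the
saliences are chosen to maximize cross-block covariance, so with noisy
blocks of this size (n = 73, 12 × 17) the latent r has an optimism floor
of roughly +0.1 near the null (measured ≈ 0.28–0.33 at ρ = 0; planted
ρ = 0.5 is recovered nearly unbiased, ρ = 0.2 lands near 0.30).  This is a
property of the estimator, not of the generator — denoising the blocks
barely moves it.  Split-half validation is the honest counterweight: it
refits the whole model in disjoint halves, and the cross-half salience
cosine / sign-agreement diagnostics (clearly labelled as extra
diagnostics, not part of the published procedure) quantify pattern
stability without in-sample optimism.

## Determinism

Every stochastic stage draws from a `SeedSequence`-spawned stream recorded
in the run manifest; the same configuration and seed reproduce cohorts,
permutations, bootstraps and reports byte-for-byte.

## Problem sizes used in verification

The shipped verification runs (test suite and `scripts/acceptance.py`) use
the generator's default cohort (n = 73, 24 × 28 × 24 grid) with 200
permutations and 100 bootstrap resamples, 200 null cohorts for
cross-sectional calibration, 100 for longitudinal calibration, 20 cohorts
per planted-effect condition, and n = 200 cohorts for the longitudinal
power check — sizes at which the calibration and recovery properties are
stable while a full verification pass stays within a few minutes on one
CPU.

## Known limitations

* Task-PLS / mean-centred contrast designs, multi-group PLS and
  lesion-subgroup analyses are out of scope.
* The default seed table for real data carries placeholder literature
  coordinates; studies must supply their own seed TSV.
* The permutation scheme permutes the behavioural block only; exchangeable
  alternatives (e.g., permuting both blocks independently) are not
  implemented.
* Imputation assumes a low-rank battery; batteries dominated by
  test-specific variance gain little over column means (though they do not
  do worse in the regimes tested).
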