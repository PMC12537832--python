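# Methods

This note documents the models, algorithms and numerical choices behind
`dgmqsm`: a synthetic-data-driven pipeline for quantitative susceptibility
mapping (QSM) of the deep grey matter (DGM) and for the statistical battery
that relates regional susceptibility and volume to clinical outcomes in an
early-multiple-sclerosis-like cohort.

## 1. Forward physics and phantoms

**Dipole model.** A susceptibility distribution χ (ppm) induces a B0 field
shift `f = IFT(D · FT(χ))` with the Lorentz-corrected unit dipole response
`D(k) = 1/3 − (k·b̂0)²/|k|²` and `D(0) = 0`. The zero DC coefficient means
the forward field of any source has zero spatial mean and the absolute
offset of χ is unobservable — the reason every map is referenced to CSF at
the end. B0 points along +z of the voxel grid; axes are RAS-like with
0-based indices; the ppm↔Hz conversion (γ̄ = 42.577 MHz/T, B0 = 3 T) is
centralized in `dgmqsm.units`.

**Phantom.** The phantom is a miniature brain on a 64³ grid at 0.75 mm
isotropic (48 mm field of view): an ellipsoidal brain compartment, a
ventricle-like CSF ellipsoid (χ = 0, the reference region), four DGM
ellipsoids — thalamus (−0.008 ppm), caudate (0.042), putamen (0.050),
pallidum (0.099), the mean values reported for early-MS cohorts — and
seeded spherical white-matter lesions (χ = 0.02 ppm) whose radii straddle
the 15 mm³ filtering threshold on purpose. Ellipsoids were chosen over
anatomical shapes because their volume is analytic, making voxelization
testable (voxel count × voxel volume vs (4/3)πabc). R2\* and magnitude are
piecewise constant per compartment, with iron-scaled R2\* in the DGM so
that magnitude contrast (and hence the TV edge mask) aligns with the true
structure boundaries, as it does in vivo.

**Signal model.** Echo j of the monopolar multi-echo GRE acquisition
(TE₁ = 6 ms, ΔTE = 6.4 ms, 6 echoes, TR = 41.75 ms, FA = 20°, 3 T) is

    S_j = m · exp(−R2* TE_j) · exp(i[φ0 + 2π γ̄ B0 f_ppm 10⁻⁶ TE_j]),

plus i.i.d. complex Gaussian noise per voxel and echo (`noise_sigma` as a
fraction of the maximum magnitude; SNR 50 ⇔ 0.02). Coil sensitivities,
k-space undersampling and physiological noise are not modelled — passing
tests therefore demonstrate correctness of the inversion chain, not
robustness to real-scanner artifacts.

**Background field.** Optional air/skull-surrogate sources (χ = 1.5 ppm)
outside the brain mask produce a genuine low-spatial-frequency background
inside it. The source strength is capped so the in-brain field stays below
the temporal aliasing limit 1/(2ΔTE): the per-voxel greedy unwrapping has
no spatial stage, so aliased inter-echo increments would be unrecoverable —
the same regime real protocols are designed for.

## 2. Reconstruction (mTFI)

**Initial fits.** Per voxel, `m` and `R2*` come from a log-linear fit to
the echo magnitudes and (f, φ0) from a |S|²-weighted linear fit to the
temporally unwrapped phase (greedy nearest-2π from echo 1). Voxels with a
zero echo magnitude are flagged and excluded.

**Edge weights.** The echo-time-weighted magnitude `W = Σ TE_j|S_j| / Σ
TE_j` emphasizes late echoes; per axis, voxels whose |∇W| exceeds the 70th
percentile of within-mask gradients are anatomical edges and get TV weight
0 (unpenalized), all others 1. A relative guard band (10⁻⁹ of the maximum
gradient) keeps tie clusters at the threshold — ubiquitous in piecewise-
constant images — on one side, which is what makes the reconstruction
invariant to round-off-level input perturbations.

**Total field inversion (TFI) initializer.** With χ = P·y and a two-level
preconditioner P (1 inside the brain, 30 outside, letting strong exterior
sources be represented cheaply), the initializer solves

    min_y ‖w (f_ppm − D ∗ (P y))‖² + λ ‖M_G ∇(P y)‖₁

over the whole field of view — there is no separate background-field
removal anywhere in the pipeline. The ℓ₁ is ε-smoothed and handled by IRLS;
each IRLS step is a conjugate-gradient solve.

**mTFI objective.** The committed data term is a magnitude-weighted
complex-exponential phase misfit summed over echoes,

    E(χ, φ0) = Σ_j ‖ w_j (e^{i(φ0 + c_j D∗χ)} − e^{i∠S_j}) ‖² + λ ‖M_G ∇χ‖₁,

with `w_j = m e^{−R2* TE_j} |S_j| / max|S|` and `c_j = 2π γ̄ B0 10⁻⁶ TE_j`.
Minimization alternates blocks: (i) `m, R2*` per-voxel magnitude refits —
they enter the phase term only as weights, so refitting them *from* that
term would be degenerate (its minimizer is m → 0); their own least-squares
subproblem is solved once and is idempotent under refits; (ii) φ0 by its
closed-form per-voxel minimizer (a weighted circular mean), which can only
decrease E; (iii) χ by a Gauss–Newton step (the linearized residual reduces
to a weighted least-squares problem on sin of the wrapped phase misfit)
with IRLS-majorized TV and CG inner solves, safeguarded by a backtracking
line search on the true ε-smoothed objective. The logged objective is
therefore non-increasing by construction, and the solver aborts loudly if
it ever is not. Iteration stops when the relative objective change falls
below `tol` (default 1e-4) or at `max_outer_iters`.

**CSF referencing.** The mean over the CSF mask is subtracted; an empty
mask yields an unreferenced map with an explicit flag.

## 3. Numerical choices that matter

* **Circulant preconditioning.** The normal operator `P C_D' W C_D P +
  λ P G' U G P` is approximated by a circulant with spatially averaged
  weights, `w̄ D(k)² + λ Σ_a ū_a s_a(k)` (s_a the forward-difference
  Laplacian symbols), and its inverse is applied as `P⁻¹ Circ⁻¹ P⁻¹` — the
  exact inverse of the circulant approximation of the *preconditioned*
  operator, so the two-level P does not degrade the circulant fit. Without
  this, CG stalls on the dipole cone and ROI means shrink by tens of
  percent at practical iteration counts.
* **Tikhonov warm start.** IRLS from a flat start is stiffest exactly at
  the start (weights ≈ 1/ε everywhere); a nearly unregularized weighted
  inversion (δ = 10⁻⁶) seeds the TV iterations and lets them converge in a
  few sweeps.
* **TV smoothing ε = 10⁻⁴ ppm.** At much smaller ε the smoothed-TV
  curvature in flat regions is too weak to control near-null dipole-cone
  modes: measured end-to-end, 10⁻¹⁵-level input rounding was amplified to
  ~3×10⁻⁵ ppm in the map. At 10⁻⁴ the global-phase-shift invariance holds
  at the 10⁻¹⁶ level and noiseless ROI recovery is exact to ~10⁻¹¹ ppm.
* **λ_tv = 10⁻⁴** (in units of the normalized fidelity), fixed once by an
  L-curve-style sweep on the default noiseless phantom and frozen; it is
  not auto-tuned per input.
* **Fixed-iteration determinism.** CG runs with an effectively unreachable
  relative tolerance (10⁻¹⁴) under a hard iteration cap, so iteration
  counts — and therefore results — are bit-reproducible for identical
  inputs.
* **Known limitation.** The convergence-tolerance stop keeps the solver
  from the exact TV-flat limit at extreme λ: at λ = 10³ the edge-masked TV
  settles ~10²–10³ × below the near-unregularized solution's rather than
  vanishing. This does not affect the operating regime (λ ≈ 10⁻⁴).

## 4. ROI metrics

Regional mean χ is the arithmetic mean over label voxels. Volumes are
head-size corrected by `raw · mean_TIV / TIV`. Lesion components use
26-connectivity; components smaller than 15 mm³ (≈3 mm diameter) are
removed, with an *inclusive* threshold (≥ 15 mm³ survives). TLV is the
surviving volume in mL and is log-transformed as `ln(TLV + 0.01 mL)`; the
offset keeps zero-lesion subjects finite and is exposed as configuration.
T1w→QSM registration and real segmentation tools are out of scope —
synthetic labels live directly in QSM space.

## 5. Cohort generator

A Gaussian latent system emulates the study's statistical structure at its
reported scale: n = 771 subjects, age 40.0 (11.0) years, 35.7% male (sex
coded female = 0 / male = 1), disease duration 7.4 (6.3) years left-censored
at 0, regional QSM and head-size-normalized volumes at the cohort means/SDs,
a 51.4% follow-up subset with intervals uniform on [1, 4.7] years, and TLV
generated log-normally so that `log_tlv` is the natural modelling scale.

Continuous covariates are multivariate normal with a configurable
correlation matrix (defaults: age–duration 0.40; basal-ganglia QSM rising
with age 0.40 and duration 0.18, thalamic QSM −0.10 with age; volumes
falling with age −0.30 and duration −0.18; QSM coherence 0.50 among basal
ganglia; volume coherence 0.40; within-region QSM–volume −0.25). The
joint distribution of the real cohort is unknown, so this matrix is
configuration, not a fidelity claim. Outcome latents are unit-variance
linear combinations of standardized predictors: `effect_map` entries are
*true standardized regression coefficients*, the residual SD is computed
analytically from the correlation matrix (an error is raised if the
combination leaves non-positive residual variance), and follow-up outcomes
add an autocorrelation term (default 0.6) on the baseline latent plus
injected baseline-predictor effects, again rescaled to unit variance.
Affine maps onto clinical scales (EDSS 1.7 ± 1.2, SDMT 60 ± 11, NBV
1418 ± 57 mL, …) are presentation only — standardized coefficients are
affine-invariant.

Default effect maps populate the battery with the reported significant
effects (e.g. caudate QSM → EDSS 0.19, thalamic QSM → log-TLV −0.07,
volume effects up to ~0.4–0.5; longitudinally volume-only prediction with
null QSM effects). Two deliberate approximations: (a) outcomes are
continuous Gaussians — EDSS's ordinal 0.5-step structure is not modelled,
matching how the regression battery treats it; (b) because regional
predictors are correlated, per-region models refit on the *default*
multi-region effect map show omitted-variable inflation (caudate-EDSS
≈ 0.24 rather than 0.19) — effect-recovery claims therefore always inject
a single effect, under which OLS is unbiased. The left-censoring of
disease duration induces a ≈ −0.01 recovery bias through its correlation
with basal-ganglia QSM; this is an honest generative/analytic mismatch and
stays well inside the ±0.03 recovery band.

## 6. Statistical battery

**Models.** Cross-sectionally, for each DGM region and each of 7 outcomes
(EDSS, T25FW, NHPT, SDMT, FSMC, NBV, log-TLV):

    outcome ~ QSM_region + volume_region + age + sex + duration     (28 models)

Longitudinally, for the 5 clinical outcomes at follow-up, adding the
baseline outcome and the follow-up interval (20 models). Continuous
variables (and the outcome) are z-scored within each model's complete
cases; sex stays 0/1, so coefficients are standardized β. VIF is computed
per model as a collinearity screen (defaults sit below 3). Zero-variance
terms (e.g. a constant follow-up interval) are excluded from the design and
reported with β = 0 and an explicit flag rather than crashing the fit.

**Permutation inference.** The paper-level choice "permutation testing" is
realized as Freedman–Lane residual permutation: for each tested
coefficient, permute the residuals of the reduced model, add them back to
the reduced fit, refit the full model and rank the observed |t| among the
permuted ones, with the `(1 + b)/(1 + B)` estimator (never exactly zero,
mildly conservative). B defaults to 10,000; the test suite uses scaled-down
counts (200–500) since only the estimator's calibration, not its
resolution, is under test. The whole permutation loop is vectorized (one
`pinv @ Y*` per term), so even B = 10,000 across all 48 models costs
seconds.

**Grouped FDR.** Benjamini–Hochberg is applied within each group of models
sharing the same outcome, separately per family, and to the effect terms of
interest (regional QSM and regional volume — the heatmap cells); nuisance
covariates are screened but not corrected. Because correction is strictly
per-outcome-group, analyses restricted to one outcome reproduce the full
battery's q-values for that outcome exactly.

## 7. Problem sizes used in tests and the acceptance script

Unit tests run on a 32³ grid at 1.5 mm (same 48 mm field of view, so the
default geometry fits); acceptance-level reconstruction runs the full 64³
default phantom, noiseless and at SNR 50. Null calibration uses 1000
replicates of n = 300 pure-null cohorts at 500 permutations (expected
rejection 25/501 ≈ 0.0499 on the attainable grid); effect recovery uses 50
cohorts of n = 771. These sizes are the package's chosen operating points
for routine verification; all are configuration, not constants.
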