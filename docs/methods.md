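# Methods

This note records the models, conventions and numerical choices behind
`pshg`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what the synthetic validation does and does not show.

## Reduced Stokes polarimetry

The instrument modelled here analyzes the SHG signal in only four
polarization states (LCP, HLP, RCP, VLP — realized by λ/4, λ/2, 3λ/4 and
λ retardances of a liquid-crystal variable retarder), so per incident
(PSG) state we reconstruct the *reduced* Stokes vector (s0, s1, s3); s2
would require ±45° linear analyzers and is not measured.  The
combination rules follow standard four-state Stokes analyzer algebra:

    s0 = (I_H + I_V + I_R + I_L) / 2
    s1 = I_H − I_V
    s3 = I_R − I_L

Two conventions are fixed here and configurable (`sign_s1`, `sign_s3`)
because an instrument's handedness may differ: s1 positive toward HLP, s3
positive toward RCP, with incident Jones vectors RCP = (1, +i)/√2 and
LCP = (1, −i)/√2 and outgoing s3 = −2 Im(PX·conj(PY)).  Under these
choices the R-ratio intermediate A(R) = ((R−1)² + 4)/(4(R−1)) is positive
for R > 1.

s0 uses the average of the two redundant estimates I_H + I_V and
I_R + I_L, which halves background noise; their absolute difference is
kept per pixel as a consistency residual (exactly zero on noise-free
synthetic data, a useful instrument QC metric on real data).

**Dark subtraction.**  `reconstruct_stokes` accepts a `dark_offset`
(mean detector background in counts) subtracted from every image before
combination.  This matters: an additive background inflates s0 but not
the differences s1, s3, so every intensity-normalized parameter is
biased — most visibly R, whose estimate is dragged toward 1 on the minus
branch.  The pipeline wires the simulator's background mean through
automatically; for real data the offset comes from a dark frame or a
background region.

## Polarimetric parameters

* **ICP** — mean of the two circular-state s0 maps.  Independent of
  in-plane fiber orientation (verified to 1e−9 against the forward
  model).
* **R-ratio** — with A = (s0^RCP + s0^LCP)/(s3^RCP − s3^LCP), R solves a
  quadratic with roots R = 1 + 2A ± 2√(A² − 1).  The two roots, R and
  1 + 4/(R − 1), produce *identical* circular-state data (same A, same
  DCP — an algebraic identity, not an approximation), so no per-pixel
  rule can choose between them from these maps alone.  The plus root is
  ≥ 3, the minus root ≤ 3.  `branch="auto"` therefore calibrates once
  per run: a probe fiber with a known ratio (default 2.0, typical for
  collagen in tissue) is simulated noise-free and the root that
  round-trips is used and recorded in the QC block.  Pixels with
  |A| < 1 (complex roots — depolarization or noise outside the
  single-fiber model) are invalidated, not clamped.
* **DCP** — mean polarized fraction of the two circular states.  Noise
  can push it above 1; such pixels are clamped to 1 and counted
  (`qc["dcp_clamped"]`), since DCP is by construction a fraction.
* **SHG-CD / SHG-LD** — normalized circular/linear intensity asymmetries,
  bounded by [−2, 2] with the extremes attained when one state's signal
  vanishes.  CD is a proxy for out-of-plane tilt (via chirality), LD for
  in-plane orientation; under unbiased sectioning their per-tile *means*
  carry little group information while their spreads (MADs) do.

**SNR mask.**  Signal pixels are selected by a background-referenced
z-score, (pixel − μ_bg)/σ_bg ≥ threshold, computed on the ICP map.
Default threshold 3 for analysis (a display threshold of 1 is also
configurable).  Background statistics come from config or from a
designated background rectangle.

## Forward model (synthetic generator)

Each fiber pixel carries a cylindrically symmetric (C6) χ⁽²⁾ tensor with
Kleinman-restricted achiral elements and one antisymmetric chiral
element; with the fiber axis ẑf at in-plane angle δ and out-of-plane
tilt α, and χzxx = 1:

    Pz = (Ex² + Ey²) + R·Ez²
    Px = 2·Ex·Ez + 2·C_eff·Ey·Ez
    Py = 2·Ey·Ez − 2·C_eff·Ex·Ez

The incident Jones field has no longitudinal component; P is rotated
back to the lab frame, the component along the propagation axis is
dropped, and the transverse components give the outgoing Stokes vector
of the coherent, fully polarized emission.  The implementation is
verified element-by-element against a brute-force rank-3 tensor
contraction with explicit numeric rotation (test oracle).

**Chiral phase.**  The chiral element enters as
C_eff = C·exp(i·φ) with φ = 90° by default.  A purely real tensor
produces exactly zero SHG-CD (swapping RCP↔LCP conjugates the incident
field, and |P| is conjugation-invariant for a real tensor), so the
quadrature phase — physically, the retardance between chiral and achiral
susceptibility components — is what lets chirality appear in the
dichroism at all.  φ = 0 recovers the purely real model.

Omitted physics: birefringence, scattering, depolarization and
focal-volume averaging.  A single fiber therefore emits DCP = 1 light;
DCP < 1 arises from incoherent summation of crossing fiber layers
(`n_layers` in the preset) and from noise.  Apparent R rises
monotonically with |α| at fixed true R (recorded as a property test;
at large tilt A → 1 and the estimate becomes noise-sensitive, a genuine
feature of this estimator).

**Fiber fields.**  Fibers are random-walk polylines (tangent-angle
Gaussian steps, SD = `orientation_dispersion` degrees per pixel step)
dilated to 2–6 px width, drawn until the pixel-density target is met;
per-pixel δ is the local tangent, while α, R and amplitude are drawn per
fiber.  Everything is deterministic given the seed (per-core seeds are
spawned from the master seed).

**Noise.**  Gaussian dark background (mean 10, SD 2 counts) plus Poisson
shot noise with a gain of 4 counts per photoelectron-equivalent;
defaults put fiber pixels near SNR ≈ 20 on the ICP map.

**Group presets** (`src/pshg/data/presets.yaml`) are *qualitative*
emulations of the normal-vs-tumor contrasts reported for breast-tissue
collagen — tumor stroma: lower SHG amplitude (25 vs 60) and fiber
density (0.12 vs 0.30), higher susceptibility ratio (R 2.2 vs 1.7, which
also raises DCP), straighter (orientation dispersion 1.5 vs 6.0 deg/step)
and less tilted (α SD 12° vs 30°) fibers, hence narrower SHG-CD/SHG-LD
spreads; normal tissue additionally gets a second crossing-fiber layer.
They are not fits to any measured dataset, and passing the synthetic
discrimination tests demonstrates pipeline correctness under this model,
not clinical performance.

## Texture analysis

Quantization bins valid pixels linearly into N_g levels (default 64)
over the per-core robust range (1st–99th percentile of valid pixels),
clipping at the ends; NaN stays NaN.  The GLCM counts pixel pairs at
offset d = 1 along 0°, 45°, 90° and 135°, skipping any pair that touches
a NaN pixel; pairs are counted in both orders (symmetric), per-angle
count matrices are averaged and then normalized.  Symmetric counting
makes the matrix symmetric, hence row and column marginals identical,
which is what makes the correlation feature well-behaved.

Feature definitions (P the normalized matrix, μ/σ the marginal
mean/SD): contrast Σ(i−j)²P; correlation Σ P(i−μ)(j−μ)/σ² (the standard
Haralick sign, so a perfectly positively correlated image scores +1; a
config flag restores the sign-flipped variant); entropy −Σ P log₂P in
bits with 0·log 0 := 0; ASM Σ P²; IDM Σ P/(1+(i−j)²).  Correlation is
reported missing when only one grey level occurs (σ = 0); all features
are missing for a tile with no valid pairs.

Per tile and parameter we also report the mean and the mean absolute
deviation about the mean over valid pixels, plus the pixel density
(count of valid pixels), for 5 × 7 + 1 = 36 features.  Tiles whose
valid fraction falls below 1 % (no viable signal) are dropped and
counted.  N_g is configurable; the `subdivision_sweep` utility plays the
analogous role for the tiling level, reporting panel means and SDs per
level so the stability/size trade-off is explicit.

## Statistics

Per feature and group, values are trimmed to the 1st–99th percentile
band (linear-interpolation percentiles, strict removal; vectors with
fewer than 10 values are passed through with a warning).  Note this
trimming is not exactly idempotent — re-application can shave a further
boundary-fraction of points, an unavoidable property of interpolated
percentiles.  Trimming applies to the testing stage only by default
(`trim_for_classification` exposes the other choice).

Group differences use the tie-corrected Kruskal–Wallis H (conventional
k − 1 degrees of freedom) and Dunn's post hoc pairwise z-tests on pooled
mean ranks with tie correction, Bonferroni-adjusted over the pairs
within each feature.  Categories: p < 0.001 highly significant,
p < 0.05 significant.  Features with no significant pair against the
reference (normal) group form the exclusion list consumed by the
classifier.  A Shapiro–Wilk report utility documents non-normality; it
gates nothing.  Under the null the adjusted two-group test is calibrated
(type-I error 5 % ± 2 % over 1000 replicates at n = 200/group — an
acceptance property).

## Classification

Plain maximum-likelihood logistic regression (no penalty; an optional
ridge term is available for separable data) on features standardized
with training-fold statistics only.  The protocol is repeated stratified
k-fold CV (k = 5): per repeat a fresh stratified split is drawn from a
repeat-specific seed, out-of-fold probabilities are pooled, and the
12-metric panel is computed once per repeat, so the SD across repeats
measures stability.  Degenerate single-class folds trigger a logged
redraw.  AUROC uses midranks (ties count ½) and is checked against an
independent implementation; Brier is the mean squared probability error.
Stratification is by class label; grouping all tiles of a core into one
fold is available but off by default, matching the treatment of each
sub-image as an independent sample.

Canonical feature subsets: (1) ICP mean + MAD + pixel density;
(2) subset 1 plus the five ICP textures; (3) mean + MAD of all five
parameters + pixel density; (4) all predictors surviving exclusion.
Held-out prediction refits once on all training rows (no CV ensemble)
and enforces that held-out core ids are absent from training.

## Problem sizes and determinism

Default synthetic study: 8 cores per group at 512² px with 8×8 tiles and
N_g = 64; CV repeats default to 1000 for production runs and are scaled
to 20 in the bundled experiments, which is ample for mean metrics while
keeping runs interactive.  All randomness flows from a single master
seed through `numpy.random.SeedSequence` spawning, so datasets, splits
and metrics are bit-reproducible; outputs embed the seed and a hash of
the analytic configuration.

## Known limitations

* The branch degeneracy of the R quadratic is resolved by calibration,
  not per pixel; samples genuinely mixing R < 3 and R > 3 regimes would
  need the linear-state data as an extra discriminator.
* The forward model omits scattering/birefringence, so synthetic DCP
  contrasts arise only from R, tilt and fiber crossing.
* Group presets are directional emulations; absolute metric values on
  synthetic data say nothing about clinical accuracy.
* The masked GLCM treats the four angle directions as exchangeable
  (direction-averaged); anisotropy-resolved texture is out of scope.
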