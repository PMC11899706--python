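# Methods

## The synthetic OCT model

The generator produces what the stability analysis needs and no more: 3D
8-bit volumes whose lesions have controllable geometry, texture, and
acquisition noise, with paired scans that share ground truth but differ the
way two consecutive OCT acquisitions differ.

A scan is rendered from a continuous model evaluated on the voxel grid
(axis order `(x, y, z)`, z = depth, default 128 × 128 × 64 voxels at
0.05 mm isotropic spacing — a desk-scale stand-in for a 6 × 6 × 1.5 mm
clinical field of view; full-size volumes add nothing to property-level
testing):

* **Background**: a depth profile `40 + 140·exp(−z/0.8 mm) +
  15·sin(2πz/0.6 mm)` plus white noise (SD 3) — exponential signal decay
  with a mild layering band, enough structure that lesion masks matter.
* **Lesion**: an ellipsoid with semi-axes `(a, b, c)` mm, `a ≥ b ≥ c`.
  Interior intensity is

  `I(p) = mean_intensity + texture_contrast · G(p) − depth_attenuation · (z − z_top)`

  where `G` is a unit-variance correlated Gaussian random field (white
  noise smoothed with a Gaussian kernel of width
  `texture_correlation_length`; the simplest field with one controllable
  spatial scale) and the linear attenuation term (default 100 gray/mm)
  models the dominant intensity gradient inside real OCT lesions: signal
  decay with depth. Without it, a lesion's intensity range is set entirely
  by its (highly variable) texture contrast, and the gray-level structure
  seen by coarse quantization bins becomes inconsistent from lesion to
  lesion — unlike real scans, where attenuation gives every ROI a wide and
  broadly similar dynamic range.
* **Speckle**: multiplicative log-normal noise with unit mean, freshly
  drawn per scan. `speckle_sd` is calibrated as the gray-value SD induced
  at intensity 128; the *realized* amplitude of each acquisition jitters
  log-normally around the nominal level (CV 0.3). The jitter matters: OCT
  noise levels depend on probe contact and coupling, and a texture
  statistic computed over ~25 000 ROI voxels self-averages, so perfectly
  level-matched speckle would leave features almost untouched however
  strong it is. Acquisition-to-acquisition level variation is the
  mechanism by which strong speckle actually degrades test–retest
  agreement. The default nominal level is low (SD 2), representing a
  multi-beam device with speckle averaging.
* **Retest transform**: the retest scan evaluates the same continuous
  model at `p' = c₀ + diag(1, 1, 1/s)(p − c₀ − t)` — a rigid translation
  `t ~ N(0, 0.05 mm)` per axis and an axial compression
  `s = exp(N(0, 0.02))` about the lesion centre, emulating probe
  repositioning and pressure. The retest mask is re-derived from the
  transformed ellipsoid, not copied, so shape features legitimately differ
  between timepoints. All-zero perturbation reduces to the identity map
  and a shared speckle stream, making the retest voxel-identical — the
  anchor for the zero-noise recovery tests.

**Between-lesion variability.** Each lesion draws its parameters around
its class template: semi-axes log-normal at 15 % CV, mean intensity normal
with the class `intensity_sd` (default 10), texture contrast log-normal at
CV 0.8, correlation length at CV 0.6. The texture spreads are deliberately
wide: lesions sharing one diagnosis span a large textural range in
practice, and this between-lesion variance is the denominator against
which a cohort-level concordance coefficient judges agreement. A cohort of
near-identical lesions would make every feature look unrepeatable (no
variance to agree about) and no texture feature reproducible across bin
widths.

**Class templates** (nevus / BCC-like / Bowen-like) differ in correlation
length (0.15 / 0.30 / 0.08 mm), contrast (12 / 25 / 18), top intensity
(120 / 155 / 90), and size ((1.5, 1.0, 0.5) / (1.8, 1.2, 0.6) /
(1.3, 0.9, 0.45) mm). These are stylized, well-separated classes — the
classifier checks test that the pipeline's moving parts compose, not that
synthetic BCC resembles histological BCC.

**What the generator does not emulate**: wave-optics speckle statistics,
adnexal structures, skin-type effects, segmentation error beyond the rigid
retest transform, device-specific intensity calibration. Passing tests
therefore demonstrate correctness and internal consistency of the
*analysis*, not clinical performance; numbers obtained on this cohort
(repeatable-feature counts, AUCs) characterize the synthetic conditions
only.

## Quantization

Fixed bin size, anchored at the ROI minimum:
`level(x) = floor((x − min_ROI)/BW) + 1`, `Ng = floor((max − min)/BW) + 1`.
Anchoring at the ROI minimum (rather than a fixed global origin) makes
levels invariant to constant intensity shifts, matching the convention of
the standard extraction toolchain. The grid of record is 5..50 in steps
of 5. First-order Entropy and Uniformity use the same discretized
histogram; all other first-order features read raw intensities.

## Feature definitions

The 107-feature default set (18 first-order, 14 shape, 24 GLCM, 16 GLRLM,
16 GLSZM, 14 GLDM, 5 NGTDM) follows the IBSI formulations as implemented
by the field's standard toolchain, including its conventions where IBSI
leaves latitude:

* GLCM and GLRLM are computed per direction over the 13 unique distance-1
  3D offsets and averaged over directions containing at least one count;
  matrices are never merged. GLCM matrices are symmetric.
* GLSZM zones and GLDM/NGTDM neighbourhoods use 26-connectivity; GLDM uses
  α = 0 (a neighbour is dependent iff its level equals the centre's) and
  dependence size `1 + #dependent neighbours`.
* Degenerate single-level ROIs: GLCM Correlation and MCC are defined as 1,
  NGTDM Coarseness is capped at 10⁶, NGTDM Contrast/Busyness/Complexity/
  Strength are 0. Skewness and Kurtosis of a constant ROI are 0. These
  conventions are tested explicitly.
* Logarithms are guarded with machine epsilon inside `log2`, as in the
  reference toolchain, so empty histogram cells contribute zero.

Shape features combine principal-axis moments (population covariance of
voxel centres in mm; axis length `4√λ`, Elongation `√(λ₂/λ₁)`, Flatness
`√(λ₃/λ₁)`) with a triangulated surface mesh. The mesh is marching cubes
at iso-level 0.5 of the zero-padded mask after light Gaussian smoothing
(σ = 0.6 voxels): meshing the raw binary grid inflates surface area ~9 %
on a digital ball (staircase artifact), which would bias Sphericity and
the surface–volume ratio; σ = 0.6 removes most of that bias while keeping
mesh volume within ~4 % of the analytic value for lesion-sized objects.
Masks too thin to survive smoothing fall back to the raw binary mesh.
Maximum 2D diameters are the largest pairwise surface-voxel distances
within planes of fixed index (Slice fixes z, Column fixes y, Row fixes x).

## Stability screening

Lin's CCC with population moments; `CCC(x, x) = 1`, symmetric, and
`|CCC| ≤ |ρ|`. When both paired samples are constant the coefficient is
0/0: such features are marked non-evaluable and excluded from repeatable
sets — agreement of constants is unmeasurable, and silently including
them would make the screen untestable. Repeatability pools all 40 lesion
pairs into one CCC per feature per bin width (one coefficient per feature
is also what a screening decision needs). The screening threshold is
inclusive (CCC = 0.9 passes).

Redundancy removal visits repeatable features in decreasing CCC (ties
broken lexicographically) and keeps a feature only if its |Spearman ρ| on
test-scan values stays below 0.9 against everything already kept —
equivalently, of any highly correlated pair the less repeatable member is
dropped. Test-scan values (not retest or averages) feed the correlation;
the choice is configurable and immaterial for strongly correlated pairs.

The consistent core is the intersection of the per-bin-width deduplicated
sets; reproducibility counts features with CCC ≥ 0.9 between the same
scans' values at two bin widths. Bin-width-invariant features (shape, and
all first-order except Entropy/Uniformity) reproduce trivially, which
puts a floor of 30 under every pair's count.

## Classification

Operating bin width 25 (a balanced middle of the grid; configurable).
XGBoost with shallow trees (depth 3, subsample 0.9, λ = 1), early stopping
(25 rounds) on an internal stratified 15 % split, stratified 70/30
train/test split and stratified 5-fold CV. The RFE arm wraps the same
learner in RFECV (one feature per step; set size chosen by 3-fold inner CV
on the training split only). The negative control permutes training labels
exactly once — the same permutation across all folds — and is evaluated
against true test labels. One permutation on ~94 training samples is a
high-variance control: its macro AUC is unbiased at chance but spreads
with SD ≈ 0.13 (measured over 20 permutations), because the permutation's
accidental cluster-level label imbalances are shared between CV-train and
validation and the learner amplifies them. CIs are stratified-bootstrap
percentiles (2 000 resamples); the bootstrap loop uses a rank-based AUC
and bincount confusion marginals identical in definition to the point
estimates.

Every source of randomness in a run — cohort, split, learner, permutation
— derives deterministically from the cohort `master_seed` through named
sub-streams, so a run is a pure function of its configuration.

## Problem sizes

Unit and property tests run on small volumes (64 × 64 × 32) and tiny
(≤ 5×5×5) brute-force-verifiable ROIs; the end-to-end suite and the
acceptance script run the full default study (80 retest scans × 10 bin
widths, 134 classification scans, four perturbation-level cohorts at bin
width 25). One complete analysis takes ~6 minutes on a single CPU.

## Known limitations

* The synthetic texture field is stationary Gaussian; real OCT texture is
  neither, so absolute repeatability counts should not be read as
  predictions for clinical scans.
* Linear intra-lesion attenuation ignores attenuation heterogeneity and
  shadowing.
* The surface-mesh smoothing trades a small volume underestimate (~4 % on
  small lesions) for unbiased surface area; both enter Sphericity.
* Feature values are validated against closed forms, brute-force
  enumerators, and conservation laws — not against the reference
  toolchain binary, which is not a build dependency.
* Subject-level splitting is not enforced in the classifier (two nevi of
  one subject can straddle the train/test boundary); synthetic lesions are
  sampled independently per lesion, so nothing leaks here, but clinical
  use would want grouped splits.
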