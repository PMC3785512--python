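# Methods

`hippoconn` is a desk-scale reimplementation of a white-matter diffusion-MRI
analysis chain: diffusion-tensor FA/MD mapping, ball-and-stick probabilistic
tractography aggregated into a seed-region ("hippocampal") structural
connectivity map, and skeleton-based nonparametric group statistics with
threshold-free cluster enhancement and permutation familywise-error control.
Every stage operates on synthetic cohorts with known ground truth, so the
whole chain is testable end to end.

## Synthetic cohorts (what the generator emulates, and what it does not)

The phantom is a 32×32×16 voxel grid at 2 mm isotropic resolution holding
tube-shaped fiber bundles (cylindrically symmetric tensors, λ∥ = 1.7×10⁻³,
λ⊥ = 0.3×10⁻³ mm²/s — a classic deep-white-matter tensor with FA ≈ 0.80),
an isotropic background (d = 0.7×10⁻³ mm²/s, grey-matter-like), and a
compact ellipsoidal seed blob abutting one bundle end, standing in for a
segmented hippocampus against its efferent tract. The default layout has
two roughly parallel bundles (one straight, one gently arced) so the
skeleton is not a single line. The seed blob holds a few tens of voxels at
this grid scale; the count is configurable and grows naturally on larger
grids.

The diffusion signal follows the multi-tensor forward model
S_i = s0 Σ_c f_c exp(−b_i gᵢᵀ D_c gᵢ) with a single-shell scheme —
b = 1000 s/mm², 32 directions + 4 b0 by default for cohort work (runtimes
in seconds), with the full 99-direction + 10-b0 high-angular-resolution
layout available and used wherever angular precision is the quantity under
study. Directions are a spherical-Fibonacci layout under a seeded random
rotation: quasi-uniform and deterministic. Magnitude noise is Rician,
sqrt((S+n₁)² + n₂²) with Gaussian channels of scale σ; cohort defaults use
σ = 0.04·s0, i.e. SNR 25 on the unattenuated signal.

Group effects scale tensor eigenvalues inside a chosen effect mask (always
a subset of bundle voxels):

- **MD elevation** multiplies every eigenvalue of every compartment by
  1 + p/100. FA is scale-invariant in the eigenvalues, so this produces the
  raised-diffusivity-without-anisotropy-change pattern characteristic of
  amnestic mild cognitive impairment.
- **FA reduction** raises the radial eigenvalues of the anisotropic
  compartment (demyelination-like loss of directionality), with the radial
  scale solved numerically (Brent bracketing) so the effective-tensor FA
  drops by exactly the requested percentage. The secondary MD increase this
  causes is physiological and is reported, not removed.

Two presets mirror the clinical patterns the generator is meant to emulate:
`amci-like` (MD +7% over a tract segment covering ~30% of the skeleton, FA
untouched) and `ad-like` (MD +8.5% and FA −11.3% over a ~2× larger
segment). Behavioural scores are drawn per subject from group-specific
normal distributions (delayed recall 12.9 ± 1.6 for controls, 6.7 ± 1.4 for
the amnestic group); they are independent of the imaging noise and exist to
exercise the amnestic classification rule (score strictly below the control
mean − 1.5 SD; the boundary itself classifies as non-amnestic).

All subjects share one grid: there is no registration stage. Ground-truth
FA/MD maps come from the fraction-weighted effective tensor Σ f_c D_c,
which is exact for single-compartment voxels; the default bundles use stick
fraction 1, making the whole phantom single-compartment and the noise-free
tensor fit exact to float precision.

What the phantom does **not** emulate — and hence what passing tests do not
establish about real data: head motion and eddy-current artefacts,
susceptibility distortion, registration error, partial-volume mixtures at
tissue interfaces, spatially varying coil sensitivity, crossing-fiber
geometry inside the cohort bundles (crossings are tested separately at the
single-voxel level), and between-subject anatomical variability.

## Tensor stage

Per in-mask voxel, the single tensor is fit by ordinary (unweighted)
log-linear least squares, ln S_i = ln s0 − b_i gᵢᵀ D gᵢ, over all gradient
entries including the b0 rows. Nonpositive signals (possible after noise)
are clamped to 10⁻⁶ of the voxel's mean b0 signal before the log, with the
clamp count logged. Eigenvalues are sorted descending; negatives are
clamped to zero (count logged), which keeps FA within [0,1]. FA and MD use
the standard eigenvalue definitions. Weighted or robust fitting variants
were deliberately not used: the unweighted fit matches the baseline
behaviour of the standard tool chain and keeps the stage deterministic.

## Ball-and-stick posterior

The voxel model is one isotropic ball plus up to two perfectly anisotropic
sticks, S_i = s0[(1−f1−f2)e^{−b_i d} + Σ_j f_j e^{−b_i d (gᵢ·v_j)²}].
A nonlinear-least-squares point fit (tensor-initialized: v1 from the
principal eigenvector, d from MD, f1 from FA clipped to [0.05, 0.95])
provides the maximum-likelihood estimate; posterior uncertainty comes from
a random-walk Metropolis sampler run simultaneously for all in-mask voxels
(component-wise updates of d, f1, f2, v1, v2; 200 burn-in iterations, 50
retained samples thinned by 5).

Priors: d uniform on (0, 5×10⁻³ mm²/s); (f1, f2) uniform on the simplex
f1 + f2 ≤ 1 with f1 ≥ f2 and a Beta(1,5) shrinkage prior on f2 — a light
stand-in for automatic relevance determination that lets the second stick
vanish when the data do not support it; orientations uniform on the sphere.
Orientation proposals are Gaussian perturbations on the sphere mixed with
an occasional (10%) uniform redraw; the redraw is a symmetric proposal that
lets chains escape the oblate-tensor plane of a 90° crossing, where the
tensor-based initialization is necessarily ~45° off both true axes. The
likelihood is Gaussian with the noise scale estimated per voxel from b0
repeats (floored at 1% of the mean b0) — a deliberate simplification of
the Rician magnitude likelihood, adequate at SNR ≥ 20.

Known behaviour worth stating plainly: in noisy single-fiber voxels the f2
posterior retains mass of order 0.05–0.1 (the Beta(1,5) prior is weak), and
individual chains can linger on the likelihood ridge where one stick splits
into two nearby ones; replicate-averaged f2 on exact data is ~0.02.
Downstream tractography prunes sticks with sampled fraction below 0.05.

## Tractography and connectivity maps

From each seed voxel, `n_samples` streamlines (default 1000; desk configs
use 200) start at uniformly jittered positions inside the voxel. One
initial orientation is drawn from the seed voxel's posterior and the two
half-tracks leave along +v and −v — seed connectivity carries no a-priori
orientation, and drawing independent first samples per half would leave
~25% of streamlines exploring only one side (posterior orientation signs
are arbitrary). At each 0.5 mm step the posterior sample for the voxel
containing the current position is drawn, a stick is chosen with
probability ∝ f_j among sticks with f_j ≥ 0.05, the orientation is folded
into the hemisphere of the current heading, and the streamline stops when
the bend cosine falls below 0.2 (≈78°), when it leaves the tracking mask,
or at 2000 steps. The per-seed map is the fraction of streamlines that
entered each voxel — a connection probability in [0,1], exactly 1 at the
seed voxel. Normalization precedes aggregation: the seed-region map is the
voxelwise **maximum** of the per-seed probability maps, read as "the
likelihood this voxel connects to any part of the seed region"; it
dominates every per-seed map pointwise and equals 1 on the seed region.

Streamline survival along a bundle decays with noise through a specific
mechanism: spurious second-stick samples (f2 just above the 0.05 floor,
random orientation) occasionally trigger the curvature stop. Geometry
oracles therefore run on noise-free phantoms (survival ≥ 0.95 over the
tube), while cohort connectivity maps at SNR 25 show the expected gradual
decay with distance from the seed.

## Skeleton statistics

The skeleton is built from the cohort mean FA: candidate voxels exceed the
FA threshold (default 0.2), and survive non-maximum suppression along a
tract-perpendicular direction estimated from the Gaussian-smoothed
(σ = 1 voxel) mean FA. The direction uses the smoothed-FA **gradient**
(the radial, center-of-gravity direction) wherever the gradient magnitude
exceeds 10⁻³ per voxel, falling back to the Hessian's most-negative-
curvature eigenvector at ridge centers where the gradient vanishes. A pure
Hessian rule is degenerate on cylindrical ridges — flank voxels' most
negative curvature is circumferential, along which they are locally
maximal, so nothing is suppressed; the hybrid reproduces the standard
skeletonization behaviour and yields 1-voxel-thin lines on tube phantoms
(with a few voxels of erosion at open tube ends, as on real data).

Projection: per skeleton voxel, the subject's maximum-FA location is
searched along ± the perpendicular direction in half-voxel steps up to
4 mm; FA projects its own maximum, and MD / connectivity values are carried
from the same FA-selected location, so all modalities are sampled at the
subject's tract center. Skeleton voxels with no positive-FA location in
range fall back to their own value and are flagged.

Inference per contrast is one-sided (patients>controls for MD,
patients<controls for FA and connectivity; each direction corrected
separately): a pooled-variance two-sample t statistic per skeleton voxel,
enhanced by TFCE — Σ_h extent(h)^0.5 · h² · dh over thresholds h in steps
of dh = max(stat)/100, with cluster extent measured by 26-connectivity
restricted to the skeleton graph (incremental union-find over descending
thresholds; verified against a brute-force threshold-and-BFS oracle to
10⁻¹⁰) — and compared against the permutation null of the maximum TFCE
score over the skeleton. All C(n, n_a) label assignments are enumerated
when they fit within the permutation budget (default 5000; desk configs
500); otherwise random relabelings are drawn. The observed labeling is
always a member of the null set and p = #{null max ≥ TFCE(v)}/n_perm, so
corrected p-values live exactly in [1/n_perm, 1] and can never be zero.

Summary metrics: the **abnormal white-matter volume fraction** is the count
of FWE-significant skeleton voxels over the skeleton size; global (whole
skeleton) and regional (significant-mask) per-subject means yield group
percent differences relative to controls and per-subject z-scores
((x − mean_CN)/sd_CN, so the controls' own z-scores have mean 0, SD 1);
z-scores are compared across groups by one-way ANOVA with Tukey HSD
post-hoc tests (one post-hoc procedure, used throughout). Statistical-map
"thickening" for display purposes is not implemented anywhere; all
quantitative outputs use un-thickened masks.

## Pipeline, seeds and problem sizes

The pipeline (library calls, numbered analysis drivers, or the `hippoconn`
CLI) chains phantom → tensor → posterior → tractography → statistics; each
stage persists its outputs, is skipped when they exist (resume), and a run
manifest records the config and SHA-256 of every output. One global seed
expands into named per-stage, per-subject and per-seed-voxel substreams
(`SeedSequence` spawn keys), so identical configs produce bit-identical
outputs and subsetting a cohort leaves other subjects' results unchanged.

Validation experiments run at fixed desk-scale sizes chosen to exercise the
statistics honestly while keeping any single experiment within minutes on
one CPU: a 64-voxel noise-free phantom for the tensor oracle; 24 replicate
voxels at SNR 20 with the 99-direction scheme for orientation recovery;
a noise-free straight tube for tracking geometry; 200 null cohorts of
8 vs 8 × 500 permutations for familywise-error calibration (measured rate
≈ 0.035–0.05 at α = 0.05); and 15 vs 15 at SNR 25 with MD +7% over ~30% of
the skeleton for effect recovery (Dice vs the injected mask ≈ 1.0, abnormal
fraction ≈ 0.30, FA contrast null).

## Limitations

- The Gaussian sampling likelihood biases d slightly at low SNR (Rician
  floor); irrelevant at the SNRs simulated here.
- Permutation inference assumes exchangeability across subjects under the
  null — satisfied by construction in the generator, but a real study
  would need covariate-aware designs (not implemented).
- The skeleton of a 2-bundle phantom is far smaller (tens of voxels) than
  a brain's (tens of thousands); permutation granularity and TFCE extent
  statistics behave accordingly, and percentages reported on it carry
  voxel-level quantization of order 1/skeleton-size.
- Connectivity maps are probabilistic visit maps, not fiber counts; no
  distance correction or waypoint constraints are offered.
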