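# Methods

## The regional-zonal model

The package represents the cerebral white matter (WM) in a
subject-specific coordinate frame with one radial and one angular
dimension.

**Radial coordinate.** The harmonic potential u solves ∇²u = 0 on the
WM domain with Dirichlet conditions u = 0 on the ventricular surface
and u = 1 on the WM/cortical-GM interface. Streamlines of
T = ∇u/|∇u| connect the two surfaces without crossing; the arc length
L₀ from the ventricular surface and L₁ to the cortical interface solve
the first-order transport equations ∇L₀·T = 1 and −∇L₁·T = 1
(Yezzi–Prince correspondence-trajectory construction). The relative
distance d = L₀/(L₀+L₁) is the normalized position along the
streamline. Because d is a ratio of lengths, it is invariant under
uniform scaling of the geometry: a subject with expanded ventricles
gets the same layer boundaries *relative to their own anatomy*, unlike
absolute mm-to-ventricle cutoffs. d is discretized into `n_layers = 4`
equidistant layers with a half-open convention — layer k covers
[(k−1)/4, k/4), with the last bin closed at 1 — so layer 1 is
periventricular and layer 4 juxtacortical.

The raw potential u is itself a monotone radial coordinate but is not
linear in physical distance on curved walls (on a spherical shell with
radii 8 and 16 voxels, u = 2/3 at the mid-wall radius where d = 1/2);
the arc-length construction is therefore the default, with
`method="potential"` available for comparison.

**Angular coordinate.** Each WM voxel takes the lobar label (frontal,
parietal, occipital, temporal × left/right) of its nearest cortical
voxel, computed with per-label Euclidean distance transforms in world
millimetres (anisotropic voxels respected) and an arg-min across
labels; exact ties resolve to the lower zone index, deterministically.
Hemisphere membership comes from the cortical parcellation's own
left/right labels, not from a mid-sagittal plane, so the assignment is
robust to head tilt. Voxels of the basal ganglia, thalami or
infratentorial structures override the lobar label with the combined
BGIT zone (zone 9). Crossing 9 zones with 4 layers yields region ids
1–36 via id = (zone−1)·4 + layer.

**BGIT radial frame.** The basal ganglia/thalami/infratentorial
subdomain receives its own radial frame: the ventricular system is
again the inner boundary and each structure's outer surface is the
outer boundary, so the four rings exist inside zone 9 as well.
Connected components with no ventricular boundary (e.g. a detached
infratentorial component) fall back to a normalized Euclidean depth
coordinate — 0 at the component's deepest point, 1 at its surface —
and the event is logged. Domain voxels missing either a layer or a
zone label (WM islands) are attached to the nearest labelled voxel,
counted and logged.

**Loads and features.** The regional WMH load is the fraction of a
region's voxels covered by lesion — an exact voxel-count ratio, so
Σᵣ loadᵣ·volumeᵣ equals the lesion volume inside the domain exactly.
The global relative burden is lesion volume over WM-domain volume (the
same frame the loads live in). Scale-specific features are
region-volume-weighted mean loads over a subscale → regions mapping.
The shipped default follows each subscale's anatomy (periventricular
items → layer-1 regions of the relevant lobes; lobar deep-WM items →
that lobe's layers 2–4; basal-ganglia and infratentorial items →
zone 9; global scores → all 36 regions) and is deliberately exposed as
configuration rather than hard-coded: which regions drive a visual
subscale is an empirical choice, not a ground truth.

## Rating scales

Three scales are encoded as machine-readable specifications with
per-subscale admissible ranges: Manolio (single global score 0–9),
Fazekas (periventricular and deep WM, each 0–3, composite = sum) and
Scheltens (periventricular frontal caps / lateral bands / occipital
caps each 0–2, total 0–6; deep WM per lobe each 0–6, total 0–24; basal
ganglia per structure each 0–6, total 0–30; infratentorial per
structure each 0–6, total 0–24). Validation reports *every* offending
(subject, rater, subscale) triple. Missing scores are explicit NaN and
propagate: a subject with any missing selected score is dropped from
that analysis with a logged count — no imputation is attempted because
how ambiguous ratings should be handled is genuinely undefined.
Consensus scores are plain arithmetic means over raters and are kept
fractional.

## Statistics

* **Correlation**: Kendall's τ-b, the tie-corrected variant — visual
  scores are heavily tied, so the tie correction matters. Implemented
  via `scipy.stats.kendalltau`; the test suite checks it against an
  independent O(n²) pair-counting oracle, exactly.
* **Confidence intervals**: subject-level nonparametric bootstrap,
  B = 1000, percentile method, seeded. Degenerate resamples (constant
  vectors) are skipped and counted. Differences of two τ statistics
  against the same score use a *paired* bootstrap (same subject
  resample for both terms).
* **Agreement**: ICC(2,1) — two-way random effects, absolute
  agreement, single measures — computed directly from the ANOVA mean
  squares, ICC = (MSR−MSE)/(MSR+(k−1)MSE+k(MSC−MSE)/n). Inter-rater
  agreement is the mean over all rater pairs; intra-rater agreement is
  the same form on two repeat measurements. The direct formula is used
  because the bootstrap and cross-validation loops evaluate it
  thousands of times; it is cross-checked against pingouin's
  ICC(A,1) to 10 decimal places in the tests.
* **Regional maps**: per-region τ-b of loads against a score vector
  (correlation map; constant regions masked), and per-region
  τ(load, one rater) − τ(load, mean of the remaining raters)
  (discrepancy map, drawn with a diverging pink/blue colormap centred
  at zero).
* **Prediction**: proportional-odds (cumulative-logit) ordinal
  regression (statsmodels `OrderedModel`), wrapped in a scikit-learn
  style estimator. Each distinct observed consensus value is one
  ordered level — averaging k raters produces multiples of 1/k, and
  treating each as a level preserves the ordering without inventing a
  rounding rule. Evaluation is stratified 2-fold cross-validation
  repeated 50 times, stratifying on outcome quartiles; out-of-fold
  predictions are compared with the actual consensus by ICC(2,1), and
  results are reported as mean (SD) with a percentile interval across
  repeats. Degenerate fits walk a deterministic ladder: more than
  `max_levels` outcome levels → quantile merge before fitting;
  separation or non-convergence → refit on ≤ 5 merged levels; still
  failing → predict the median level. Every fallback is logged.
* **Multiple testing**: none is applied; all intervals are
  per-comparison.

## The synthetic-data generator

`generate_phantom` builds a label-space head: nested ellipsoidal
shells (ventricles; WM; a cortical shell split into 8 lobar sectors by
hemisphere and angular quadrant — frontal anterior, parietal superior,
occipital posterior, temporal inferior), thalamus and basal-ganglia
blobs touching the ventricular surface, and an infratentorial blob
placed below the cerebrum, detached by default so the Euclidean
fallback path is exercised. Spherical configurations emit the analytic
relative distance (r−r₀)/(r₁−r₀) as a closed-form oracle.

`plant_lesions` grows random spherical blobs (radius 1.5–4 mm) inside
each region until round(target·|region|) voxels are lesioned, trimming
the last blob rim-first so the achieved count is exact; the *achieved*
fractions are returned as ground truth, making the round trip through
`compute_regional_loads` exact by construction rather than
approximately correct.

`simulate_cohort` draws per-subject 36-vectors of target fractions
from a logit-normal family: logit(f) = −4.8 + layer offset
(+2.0, +0.3, −0.6, −1.2 from periventricular to juxtacortical) + zone
offset (+0.9 frontal, +0.2 parietal, 0 occipital, −0.7 temporal, −1.8
BGIT, identical left and right) + subject severity N(0, 1.1²) + region
noise N(0, 0.5²). These defaults produce the qualitative profile seen
in elderly cohorts — periventricular-dominant, frontal-weighted,
left-right symmetric in expectation, infratentorial sparing — with
median total burdens around 1–2 mL at the default geometry.

`simulate_raters` scores the cohort through noisy monotone functions:
a rater's raw value for a subscale is the weighted mean load over the
subscale's regions (weights = that rater's 36-vector of regional
sensitivities), perturbed by Gaussian noise (SD expressed as a
fraction of the cohort raw-score SD, default 0.2) and thresholded into
the subscale's range at cutpoints anchored to cohort quantiles shared
by all raters. `planted_bias_scenario` boosts one rater's weight on
the frontal juxtacortical regions (×8) against a cohort drawn with
more independent regional variation (subject SD 0.6, region SD 1.0);
a regional bias is only identifiable when regions vary somewhat
independently of overall severity, and under the heavily
severity-driven default profile the discrepancy map correctly shows
little localized signal.

**What the phantom does not emulate**: MR intensities and segmentation
error (inputs are perfect labels), realistic lesion morphology beyond
blob unions, gyral folding and convoluted ventricular horns, rater
drift over time, and the size/count criteria of the Scheltens scale
(the load feature is a pure volume fraction). Passing tests therefore
demonstrate correctness of the geometry, bookkeeping and statistics —
not robustness to segmentation noise on clinical images.

## Numerical choices

* Laplace solver: 6-connected finite differences, red–black
  Gauss–Seidel with over-relaxation (ω = 1.9), initialized from the
  normalized Euclidean distance ratio; default tolerance 1e-5 on the
  maximum residual, cap 5000 iterations (error on non-convergence).
  Neighbours outside the solvable set act as Neumann (reflecting)
  boundaries. Domain components with no path to either surface are
  excluded with a warning.
* Transport solver: first-order upwind fixed-point sweeps; seeds carry
  −h/2 during iteration so arc lengths measure to the boundary *face*
  rather than the boundary voxel centre (on a 10-voxel slab
  L₀+L₁ = 10, not 11). Zero-gradient voxels and the complementary
  length on each boundary are filled from the nearest solved voxel and
  counted.
* Solvers run on the domain's bounding box (+2 voxels) for speed;
  results are pasted back into the full grid.
* On the 96³ spherical-shell phantom the relative distance matches the
  closed form with MAE ≈ 0.016 (the residual is voxelization of the
  boundary surfaces, not solver error; it shrinks with wall
  thickness).
* All stochastic procedures take a seed; the study driver spawns child
  seeds (NumPy `SeedSequence`, kept below 2³¹) per subject and stage,
  so outputs are bit-reproducible and adding subjects does not perturb
  earlier ones.
* Rendering: wedge geometry is drawn clockwise from the top in the
  mirror-symmetric order Front-L, Front-R, Par-R, Occ-R, Temp-R, BGIT,
  Temp-L, Occ-L, Par-L (configurable); SVG output pins the hash salt
  and omits the creation date, so repeated renders are byte-identical.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` use a 96³ grid for the
oracle and study checks (20 subjects in the full synthetic study, ~4 s
per subject for the complete parcellation), 48³ phantoms for the
20-phantom round-trip sweep, n = 200 subjects × 50 seeds for the ICC
recovery experiments, and 50-repeat 2-fold cross-validation with
100–120 subjects for the prediction comparisons. These sizes give
Monte-Carlo error comfortably below the margins asserted.

## Known limitations

* The subscale → region mapping is a declared convention; predictions
  for a real cohort depend on how well it matches the raters' reading
  of the scale definitions.
* The correlation analyses inherit τ's insensitivity to the
  ceiling/flooring typical of visual scales at high burden.
* The discrepancy maps estimate per-region rater bias marginally; they
  do not model associations between regions.
* The cumulative-logit model assumes proportional odds across score
  thresholds; an adjacent-category formulation is a plausible
  alternative that is not implemented.
* Lesion counting/size features are out of scope; only the volume
  fraction is computed.
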