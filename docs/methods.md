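# Methods

This note documents the models implemented in `tractstim`, their
assumptions and parameter defaults, the design choices made where the
design was genuinely open, and what the synthetic cohort does and does not
emulate. All empirical statements below are recomputed by the test suite
or `scripts/acceptance.py`; nothing here is quoted from elsewhere.

## Lead geometry

`LeadModel` describes an 8-contact directional lead in the 1-3-3-1 layout
(Boston Scientific Vercise Cartesia class): a distal ring (contact 1), two
levels of three 120°-spaced segments (contacts 2-4 and 5-7), and a
proximal ring (contact 8). Geometry constants: contact length 1.5 mm,
inter-contact gap 0.5 mm (2.0 mm level pitch, level centroids at 0.75,
2.75, 4.75, 6.75 mm above the tip along the axis), lead radius 0.635 mm.
The pose is (tip position, unit axis distal→proximal, rotation of the
marker direction about the axis); segment centroids are displaced one lead
radius along their outward normal. Numbering is distal-first; ties and
"more distal" preferences throughout the package refer to this order.

Configurations are `C1`–`C8` (single contacts) and `L1`–`L4` (levels:
rings at 1 and 4, pseudorings — all three segments driven together — at 2
and 3).

## VTA kernel

The stimulated volume is modelled as a thresholded electric field. The
finite-element machinery of clinical VTA pipelines is out of scope here;
the kernel is the homogeneous point-source closed form

    E(r) = I / (4π σ r²)  ⇒  r(I) = sqrt(I / (4π σ E_t)).

Defaults: σ = 0.33 S/m (grey matter; a white-matter value 0.14 S/m is
accepted in `VTAParams` but unused — a homogeneous kernel has one σ) and
E_t = 0.2 V/mm. With these, r(1 mA) ≈ 1.098 mm and radii scale with √I
(r(8 mA) ≈ 3.11 mm), which is the clinically sensible millimetre scale; a
threshold read as 0.2 V/m would give centimetre-scale volumes, so the
V/mm convention is the default. The kernel field in `VTAParams.kernel` is
a seam for alternative closed forms.

Directional contacts clip the sphere to an angular sector about the
contact's outward normal, full width `sector_width_deg` (default 180°:
the 120° contact span plus spread margin; 360° degenerates to the full
sphere). Pseudorings are modelled as a ring source at the level centroid
carrying the full amplitude — no current-splitting rule is imposed. For a
fixed configuration the centre and sector do not depend on amplitude, so
VTAs are nested in amplitude by construction.

VTAs can be rasterised to NIfTI masks (voxel centres inside the analytic
volume, default 0.2 mm isotropic) for interoperability.

## Pathway activation

Activation of a bundle in a VTA is the weight fraction
Σ{w_s : s hits V} / Σ w_s. A streamline "hits" when any polyline
*segment* intersects the volume, not when a vertex happens to fall inside:
for spheres this is an exact point-to-segment distance test; for sector
spheres the minimum distance from the centre to the part of the segment
satisfying the angular constraint is found in closed form (the constrained
minimiser lies at an interval endpoint, the unconstrained minimiser, or a
root of the cone-boundary quadratic — all enumerated and checked). Mask
VTAs use the voxel-lookup convention instead, after densifying segments to
half a voxel; this reproduces vertex-in-voxel behaviour of image-based
toolchains, and both routes are cross-checked in tests.

Because the sector is amplitude-independent, each streamline has a
*critical radius* — the smallest kernel radius that reaches it — computed
once per (lead, configuration, bundle). Activation profiles over the
amplitude grid are then threshold comparisons against r(I), which makes
monotonicity in amplitude structural rather than numerical.

Activation is computed per hemisphere: a lead only sees the bundles of its
own side (cross-hemisphere activation is defined as 0).

## Stimulation models

One binary logistic model per pathway on the untransformed activation
fraction a ∈ [0, 1]:

    p(effect | a) = logistic(β₀ + β₁ a).

Training set, per tested configuration of every lead: one negative at
0.5 mA (minimal activation below any clinical response — using 0 mA would
put all negatives exactly at zero activation), and one positive at the
recorded threshold (effect threshold for the HDP model, side-effect
threshold for the CST model) when that threshold was reached within the
sweep. Censored thresholds (`">8"`) contribute no positive; untested
configurations contribute nothing.

Fitting is scikit-learn L2-penalised logistic regression. The inverse
penalty C is selected from a log grid {0.01, 0.1, 1, 10, 100, 1000} by
subject-grouped inner cross-validation (GroupKFold, up to 5 groups)
maximising balanced accuracy; the outer loop is leave-one-subject-out.
Classification uses cutoff 0.5 with ties going to "effect". The model
card reports β₀, β₁, exp(β₁), the boundary −β₀/β₁, and the inverse
activation at p ∈ {0.5, 0.95, 0.99} rather than fixing one "certainty"
probability. The pooled LOSO estimate of the boundary is the mean of the
per-fold boundaries. The fold aggregate carries a normal-approximation
95% CI across folds.

Degenerate inputs: single-class training sets raise; LOSO folds whose
training set collapses to one class are skipped with a warning; fewer
distinct subjects than inner folds shrink the split, and a single subject
falls back to the middle of the penalty grid.

## Suggestions

Per configuration the suggested (side-)effect threshold is the lowest
amplitude on the 1–8 mA grid whose activation the model classifies as
effect; censored if none. Strategies for best level (over `L1`–`L4`) and
best contact (over `C1`–`C8`):

* **initial** — lowest suggested effect threshold; worst level/contact
  analogously from the CST model (lowest side-effect threshold).
* **combined** — keep configurations with effect ≤ side-effect + 1 mA
  (side effects must not precede full effect by more than one step;
  censored side-effect keeps, censored effect excludes), then lowest
  effect threshold.
* **window** — widest therapeutic window, side-effect − effect threshold,
  with a censored side-effect entering as 8.5 mA (one grid step past the
  sweep end, preserving order without inventing an observation).

Tie-breaks are deterministic and logged in the code: wider window, then
lower effect threshold, then the more distal configuration (for worst
picks: narrower window, then more distal). Suggestions are therefore
invariant to enumeration order.

## Evaluation

Balanced accuracy 0.5·(TP/(TP+FN) + TN/(TN+FP)) over per-lead one-hot
vectors (4 entries per lead for levels, 8 for contacts; a lead with no
clinical label is dropped, a lead whose suggestion is censored contributes
all-zero suggestion entries). Significance: right-tailed permutation test
shuffling the *suggestion vector* uniformly (default 100 000 permutations,
chunked and seeded); the p-value uses the add-one correction
(1 + #{≥ observed}) / (1 + n) so it is never 0, with a flag for the plain
fraction. A within-lead permutation mode exists for sensitivity analysis;
the global shuffle is the default because the suggestion vector is
permuted as a whole. Under the global shuffle the expected balanced
accuracy is exactly 0.5 for any marginals — the reference against which
"better than chance" is meaningful. Shuffling *clinical labels across
leads* is not equivalent: both clinical and suggested best levels
concentrate near the dorsolateral target, so a label shuffle retains
marginal-alignment agreement above 0.5; the test suite asserts separation
from the informative accuracy for that shuffle and exact-chance behaviour
for the vector shuffle.

Threshold errors are signed (suggested − clinical) and absolute
differences over pairs where both sides are uncensored (exclusion counts
reported; no numeric difference exists for `">8"`), summarised by medians
and grouped per lead. Contact distances (same-level flag, centroid
distance) quantify near-misses of best-contact suggestions.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, in
world millimetres (MNI-like axes), with these defaults:

* **STN**: axis-aligned ellipsoid, centre (±12, −13, −7) mm, semi-axes
  (3, 5, 3) mm — long axis anteroposterior, lateral/vertical half-width
  3 mm — with the dorsolateral direction (±1, 0, 1)/√2 and a 45° half-angle
  dorsolateral sector. The lateral-thin orientation is what makes a
  capsule tube that never enters the nucleus geometrically compatible with
  clinical side-effect distances.
* **HDP** (default 500 streamlines): quadratic-Bezier polylines from an
  8 mm cortical disc at (±28, 15, 55) to endpoints inside the dorsolateral
  sector, each fibre descending its own laterally scattered corridor
  (σ = 4 mm) so the funnel is loose near the lead and tight at the
  nucleus; steps ≤ 1 mm, lengths ≤ 90 mm.
* **CST** (default 2000 streamlines): a near-vertical tube (radius
  1.5 mm) whose core passes 4 mm posterolateral to the dorsolateral pole
  with a slight outward lean, spanning z = +45 to −60 (lengths within
  [80, 135] mm) and never entering the ellipsoid.
* **Weights**: log-normal(μ = 0, σ = 0.8) — heavy-tailed, as
  tractogram-filtering weights are.
* **Leads**: canonical trajectory (0.2, 0.35, 1)ₙₒᵣₘ targeted 2 mm above
  the dorsolateral pole, isotropic jitter σ = 1 mm plus axial
  implant-depth jitter σ = 2 mm (real cohorts differ in depth by
  millimetres; without it one level is best for over half the leads),
  axis tilt ≤ 10°, uniform rotation. Placements whose contact span comes
  within 1.7 mm of the tube edge are resampled — surgical planning avoids
  capsule-piercing trajectories, and without this constraint jittered
  leads land inside the tube and produce implausible 1 mA side-effect
  thresholds en masse.
* **Ground truth**: logistic responses with boundaries a₅₀ = 0.10 (HDP;
  β = (−1.15, 11.5), so ~50% activation gives p ≈ 0.99) and a₅₀ = 0.01
  (CST; β = (−1.533, 153.3), p ≈ 0.99 at 4% activation).
* **Review simulation**: per configuration the true threshold is the first
  grid amplitude whose ground-truth probability reaches 0.5; observed
  thresholds jitter by one grid step with probability 0.2 (noise acts on
  thresholds, not per-amplitude draws, preserving the monotone structure
  of a monopolar review), clip to 1 mA, censor past 8 mA. The sweep
  aborts — censoring the effect threshold — when the side effect comes
  strictly first; the abort is part of the review protocol and therefore
  also applied to the recorded truth, so noiseless runs reproduce it
  exactly. Directional contacts are untested with probability 1 − 0.608.

These defaults were calibrated once against clinical plausibility of the
simulated review — median effect thresholds near 2–3 mA, side-effect
thresholds above them, roughly 40% censoring — and then frozen.

What the generator does **not** emulate: real cortical anatomy or atlas
geometry, fibre curvature of the internal capsule, inter-subject variation
of STN shape, dMRI noise or tractography false positives, axon-diameter or
orientation-dependent activation thresholds, and any coupling between
pathways beyond shared geometry. Passing tests therefore show that the
pipeline recovers a known dose-response from review-structured, censored,
noisy data under the stated geometry — not that the specific accuracy
numbers transfer to patient data.

## Problem sizes and numerical choices

The test suite and acceptance script run the full design at the study
scale (20 subjects, 40 leads, 500/2000 streamlines) with fixed seeds;
component tests use reduced bundles (tens to hundreds of streamlines),
which the generator exposes as ordinary parameters. Permutation tests use
100 000 permutations in the acceptance script and smaller counts in unit
tests. Geometry is exact (closed-form quadratics with a 1e-9 feasibility
tolerance at cone boundaries); the only discretised routes are the
optional mask VTAs (0.2 mm voxels by default) and the dense-resampling
oracles used in tests (0.01 mm). Logistic fits use lbfgs with
max_iter = 5000. All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); cohort entities are seeded per subject and
hemisphere so cohorts are reproducible element-wise.

## Known limitations

* The point-source kernel ignores tissue heterogeneity, anisotropy and
  electrode geometry; radii at high amplitude are optimistic.
* The 180° sector is a coarse stand-in for directional field shaping.
* Pseudorings carry the full amplitude at the level centroid; no current
  division across segments is modelled.
* The logistic models are univariate by design; interactions between
  pathways (or additional pathways) are out of scope.
* Balanced accuracies measured on the synthetic cohort are higher than
  one should expect on patient data: the generator's world is cleaner
  than reality by construction.
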