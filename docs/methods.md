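# Methods

This note records the models implemented in `dermopt`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not establish.

## Q-learning segmentation

**Problem setup.** An image is smoothed with a disk-neighborhood mean filter
(all pixels at Euclidean distance < n from the center; n = 0 disables
filtering and n ≤ 1 is the identity, since only the pixel itself lies
within distance 1), then tiled row-major into sub-images with clipped edge
tiles. Per sub-image the agent chooses an action (τ, ν): the mask is
"intensity ≤ τ" (lesions are darker than skin) followed by morphological
opening with a disk of radius ν. Thresholds are stored as indices into 8
evenly spaced levels over the sub-image's [gmin, gmax] so one strategy
table transfers across sub-images; for a constant tile (gmin = gmax) the
first level drops below gmin so the policy can produce the empty mask. The
state discretizes area fraction, compactness 4πA/P², capped
connected-component count and the tile's image quadrant into
(9, 5, 4, 4) bins (Mode 1) or (4, 4, 3, 3) (Mode 2); the two modes are
exposed as a configuration switch.

**Episode structure.** The literature this follows names the learning
algorithm but not the episode design, so the package defines one: an
episode starts from the canonical full-mask action (highest threshold, no
opening) and applies ε-greedy actions; an action that strictly reduces the
dissimilarity D earns R1 = +1 and the episode continues from the new mask's
state, any other action earns R2 = −1 and terminates the episode (the
Q-update then uses the plain reward, no bootstrap). Under this structure
Q(s, a) > 0 marks actions that improve from state s, so the greedy policy
is a hill-descent on dissimilarity with a learned stopping rule: at
inference it follows argmax actions while their value is positive and stops
at a predicted local minimum or a mask fixed point. At convergence every
stopping mask is one no single action improves upon, i.e. a
minimum-dissimilarity action's mask — which is why the trained policy can
be held to the "no worse than the best fixed action" bound that the test
suite checks by exhaustive action sweep.

Defaults: learning rate 0.1, discount 0.9, ε decaying 0.5 → 0.05, 50
passes over the training stream, episode/rollout cap 8 steps, reward ±1.

**Dimension selection.** One agent per candidate tiling trains on the same
images; after each image the control agent kills any agent whose
dissimilarity rose over three consecutive records and, at the end of each
pass, the live agent with the worst current dissimilarity (ties to the
lowest id, never the last survivor). Because different tilings produce
different sub-image counts, agents are aligned and compared per *image*
(mean dissimilarity over that image's tiles). Candidate tilings default to
16/32/64-pixel squares clipped to the image.

**Post-processing.** Opening-then-closing with a disk whose radius is the
argmin of mean training dissimilarity over candidates {1..5}, ties to the
smallest.

**A discretization caveat.** Morphological opening with a rasterized disk
structuring element perturbs an ideal rasterized disk by ~8 boundary pixels
at many fractional radii. Masks differing by a few boundary pixels fall in
the same state bin, so their actions' Q-values converge to the same limit
and the tie is resolved by training noise. The policy-versus-fixed-action
bound is therefore checked under conditions where the bound is a property
of the method rather than of structuring-element rasterization: noise-free
binary disks, no smoothing (none is needed without noise), and the
threshold sweep as the action lattice.

## Feature extraction

Computed on the largest 8-connected component of the mask. Major/minor
axis lengths a, b are the pixel-coordinate extents along the principal
(second-moment) axes — for an axis-aligned h×w rectangle exactly
max(h, w) and min(h, w), which keeps rectangularity A/(a·b) equal to 1 for
rectangles (moment-ellipse axis lengths would not). Perimeter is the
scikit-image 4-connectivity boundary-length estimator, ≈ 2πr for digital
disks, so the irregularity index 4πA/P² ≈ 1 for circles; the test oracle
is an independent Moore boundary trace. A legacy formulation of elongation and eccentricity (2A/(aπ) and
2a(a²−b²)) circulates in this method family but is dimensionally
inconsistent; the standard b/a and √(a²−b²)/a are the defaults, with the
legacy forms available behind `FeatureConfig(legacy_formulas=True)`.
Contrast is the standard Σ(i−j)²p(i,j).

The GLCM uses 8 quantized levels and offset (0, 1), counts only pixel
pairs whose both endpoints lie inside the mask (hence a direct count —
`graycomatrix` cannot mask), symmetrized and normalized. Homogeneity
uses the Σp/(1+|i−j|) form (scikit-image's divides by 1+(i−j)²); correlation of a constant region is reported as NaN and imputed
by column medians before selection/classification. Entropy is log base 2
over the histogram of rounded masked intensities with 0·log 0 := 0. Hu
invariants use normalized central moments η_pq with
φ3 = (η30 − 3η12)² + (3η21 − η03)².

## Fish migration optimization

Each fish holds a position, previous position, an energy budget (initial
value 2), and an age stage 0–4 with counts in ratio 1:1:1:0.66:0.66
(largest-remainder rounding) and survival rates (1, 0.93, 0.91, 0.37,
0.66). Per iteration: migrating fish (stage ≥ 2) lose the normalized
fitness share f_j/Σf (skipped when Σf = 0); fish that improved their
personal best regain r1·E_init (the "finer solution expands the fish's
power" rule, operationalized as personal-best improvement); per-stage
Bernoulli survival with dead fish replaced by fresh uniform newborns
(population size strictly conserved); survivors contract toward the global
best Z ← gb + r2(Z − gb); stages 2–3 then move by
Z ← Z + orispeed·consumption + E_init·r4·(gb − Z) with
orispeed = ±(Z − Z_prev) by the sign draw r3 and consumption = E_init·r4
while energy lasts, else energy·r6 — the update is an increment, so a fish
at the global best with no momentum stays put. Stages 0, 1, 4 use the
contraction rule. Positions are clamped to the box; fish age one stage
every ⌈max_iter/5⌉ iterations and stage-4 survivors restart at stage 0
with fresh energy. Elitist best-so-far tracking makes the reported
trajectory non-increasing.

**Enhancements.** Opposition-based learning reflects a candidate to
lo + hi − x and keeps the better of the pair; it is applied to 30% of the
initial population and to every newborn (newborns are freshly generated
random candidates, exactly the objects the opposition rule is defined on).
The chaotic sine stream r ← (γ/4)sin(πr), γ = 4, substitutes for (a) the
energy-recovery draw r1 and (b) the newborn samples after the global best
has stalled for 5 iterations — chaotic individuals in place of stochastic
individuals, the escape mechanism chaos is meant to provide. The
contraction and attraction coefficients r2, r4, r5 deliberately stay
uniform: the sine map's invariant density piles mass near 0 and 1, and
feeding it to contraction coefficients systematically slows convergence
(measured on all four benchmarks). The survival lottery likewise stays
uniform — it realizes a population expectation, not one of the update
draws. Auxiliary enhancement randomness comes from a spawned RNG stream
and chaotic values replace a still-consumed uniform draw, so the enhanced
and plain variants share an identical main draw sequence per seed and
ablation comparisons are paired.

**Benchmarks.** F_k(x) = f_k(M(x − o_k)) + 100k on [−100, 100]^d with a
seeded QR-orthogonal rotation M and a shift drawn within 80% of the box;
the Rosenbrock form maps M·2.048(x − o)/100 + 1 so the optimum sits at
x = o with value 400. Absolute benchmark scores depend on the specific
rotation/shift realization, which this package generates from seeds; the
harness therefore checks the directional claim (enhanced ≤ plain on the
10-run mean of each function, d = 10, population 30, 60 iterations —
scaled down from the 70-fish/200-iteration default so the whole suite runs
quickly on one CPU; the direction was additionally verified with 100 runs
per function).

## Feature selection and SVM tuning

The selection cost α·accuracy + β·(selected Fisher-score sum / total sum)
with α = 0.65, β = 0.35 is *maximized*: larger accuracy and larger
selected-score share are unambiguously better, so the optimizer runs on
the negated cost. Accuracy is 5-fold stratified CV of a
fixed-parameter RBF SVM (C = 1, gamma = "scale") on standardized selected
features. Fisher scores with zero within-class variance are infinite
sentinels, capped at 10× the largest finite score inside the ratio.
EFMO searches [0, 1]^Nb thresholded at 0.5; empty masks are repaired by
activating the top-Fisher feature; mask costs are memoized. Defaults:
population 30, 30 iterations — enough for the ≤ 2^10-mask spaces used in
testing to come within 1% of the exhaustive optimum.

SVM tuning runs EFMO twice: log10 γ ∈ [−4, 2] at C0 = 1, then log10 C ∈
[−2, 4] at the frozen γ* (one round by default; `rounds` repeats the
alternation). CV accuracy is cached on a 10⁻³ grid of the log-parameter —
it is a step function of the parameter, so this loses nothing. The final
model stores its scaler statistics, support vectors, dual coefficients and
bias, and is JSON-serializable; predictions use the dual-form decision
function directly.

## Synthetic data

A lesion is a radially perturbed disk r(θ) = r0(1 + irregularity·s(θ))
with s a random 4-harmonic trigonometric polynomial normalized to
max|s| = 1, drawn dark on a lighter uniform background with clipped
additive Gaussian noise. The two-class image generator contrasts round,
lighter lesions (irregularity 0.05, intensity 110) with irregular, darker
ones (irregularity 0.55, intensity 60), both at noise SD 6 on 64×64
frames — the geometry/intensity contrast the features are designed to
detect. Feature tables plant a mean shift of `class_separation` on chosen
informative features, all others identically distributed.

What this does *not* emulate: hair and ruler artifacts, color, specular
highlights, skin texture beyond white noise, multi-modal lesion
intensities, or class overlap in feature space. A perfect held-out score
on the synthetic classes therefore demonstrates that the pipeline's
stages compose correctly and recover planted structure — not clinical
performance. Published scores on real dermoscopy corpora require those
corpora and their splits.

## Problem sizes in the test suite

Chosen so the full suite runs in minutes on one CPU: segmentation training
on 6 noise-free 48×48 disks (40 passes); the end-to-end run on 30 training
and 40 held-out 64×64 images; the ablation at d = 10 with population 30,
60 iterations, 10 paired seeds per variant; selection recovery on
19-feature tables with 40 samples per class; exhaustive selection oracles
at 10 features.

## Known limitations

- The strategy table is tabular; images whose sub-image statistics fall in
  state bins never visited during training fall back to zero-valued
  entries (the rollout then stops at the canonical action's mask).
- Dissimilarity weighs lesion and background pixels equally, so tiny
  lesions give near-zero D even for empty masks; the pipeline guards with
  a darkest-quartile fallback when a segmentation comes out empty.
- The optimizer ablation is a directional property of means under paired
  seeds; individual runs of a stochastic optimizer on ill-conditioned
  landscapes vary by orders of magnitude.
- Mode 1/Mode 2 state discretizations are implemented as alternative
  configurations selected up front, not as sequential stages.
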