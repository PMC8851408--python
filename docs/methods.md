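# Methods

This note records the models behind `focalstim`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical choices that matter.

## Stimulus parameterization

A stimulus is a 5 s train of charge-balanced, anodic-first biphasic current
pulses at 120 Hz. The cathodic phase is fixed at 100 µs and the interphase
gap at 5 µs (carried as metadata; it affects no computation here). Two
parameters vary:

* **cathodic amplitude** `a` in µA;
* **pulse type** `t` ∈ {1,…,5}, the ordinal index of the anodic/cathodic
  duration ratio in {1, 2, 5, 10, 20}. Charge balance fixes the anodic
  amplitude to `a / ratio`, and the 1 µA stimulator resolution therefore
  requires `a` divisible by the ratio.

The experimental grid steps `a` by 10 µA across a per-region window
(default 20–110 µA, alternatively 40–130 µA) for ratios 1–10 (10 amplitudes
each) and restricts ratio 20 to multiples of 20 µA in a 20–130 µA window
(6 amplitudes), i.e. 46 combinations. The exact six ratio-20 amplitudes
used experimentally are not published; multiples of 20 µA are the unique
choice consistent with integer anodic current and the printed count, and we
adopt them. During optimization `t` is treated as a continuous coordinate
on [1, 5] (the type axis is evenly spaced ordinal, matching how objective
maps are drawn at "resolution 1"), and both coordinates are rounded to the
nearest deliverable setting only when a stimulus is actually delivered.

## Imaging model

Recordings are 10 frames/s, 5 s pre-stimulus + 5 s during stimulus. The
baseline image averages frames 2–3 s after recording onset and the stimulus
image averages frames 2–3 s after stimulus onset (frame indices [20, 30)
and [70, 80), half-open). ΔF/F is computed pixelwise against the baseline
image; pixels with non-positive baseline are masked out and counted. The
active mask is ΔF/F > 0.15, a threshold set to sit well above typical
fluorescence noise.

The response shape is the **moment-based equivalent ellipse** of the active
pixel set, treated as a single point set (no connected-component
selection — one ellipse per image). With second central moments' eigenvalues
λ₁ ≥ λ₂, the semi-axes are p = 2√λ₁, q = 2√λ₂ (exact for solid ellipses);
activation area is πpq·(pixel size)² and eccentricity √(1 − (q/p)²), which
equals the focal-distance / major-axis ratio. A half-pixel variance (1/12
per axis) is added so single pixels and 1-px bars have finite extent. The
fitting method is a design choice (the equivalent alternative would be
contour least squares); the moment fit is deterministic and robust for
filled regions. Empty masks carry (area 0, eccentricity 0) sentinels; class
assignment keys on the active-pixel count, not the sentinels.

## Response classes

| class | semantics | rule |
|---|---|---|
| 0 | no meaningful activity | active pixels < 5 |
| 1 | round and small | E < 0.5 and area < 2× electrode area |
| 2 | elongated and small | E ≥ 0.5 and area < 2× electrode area |
| 3 | round and large | E < 0.5 and area ≥ 2× electrode area |
| 4 | elongated and large | E ≥ 0.5 and area ≥ 2× electrode area |

2× the electrode area (electrode diameter 200 µm, area π·100² ≈ 31 416 µm²)
marks overlap with neighboring electrodes at the 500 µm array pitch; 0.5 is
the midpoint of the eccentricity range. The published rules use strict
inequalities on both sides and leave equality undefined; we assign equality
to the elongated/large side and test the exact boundary points. The 5-pixel
floor operationalizes the manual relabeling of sparse (1–2 cell) images as
"no meaningful activity": an ellipse fit through a handful of pixels is
formally valid but not a meaningful spatial response.

## Synthetic retina

Each region draws, from a seeded generator:

* per-type **threshold amplitudes** (base U(25, 65) µA ± 5 µA per type) —
  below threshold the response is exactly zero;
* an **area surface** A\*(a, t) = A_min + (A_max − A_min)(1 − e^−(a−thr)/τ)
  above threshold, with A_min ~ U(800, 2000) µm² (one to a few somas),
  A_max ~ U(1.5, 3)× electrode area, τ ~ U(25, 60) µA — saturating and
  monotone in amplitude;
* an **eccentricity surface** E\*(a, t) decreasing with type (0.05–0.10 per
  type step: high-duration-ratio asymmetric pulses are more soma-selective,
  hence more focal) and increasing with amplitude (0–0.35 across the
  window: stronger fields capture passing axons), clipped to [0, 0.97).
  The eccentricity of the most focal stimulus (type 5 near threshold) is
  drawn U(0.25, 0.85), straddling the 0.5 class boundary so that a region's
  best attainable class is 1 for some regions and 2 for others — matching
  the observed repertoire of real regions, where every region topped out at
  class 1 or 2 (7 vs 17 of 24 in the reference dataset; the default
  generator happens to reproduce that split over seeds 0–23, which we
  report as an observation, not a calibration);
* an **axon orientation** U(0°, 180°) and a small soma-center jitter
  (σ = 8 µm).

Rendering places an elliptical ΔF/F footprint (peak 0.6) with the target
area/eccentricity, oriented along the axon, with a logistic edge whose 0.15
contour is calibrated to enclose exactly the target ellipse, plus a
brighter soma core. Frames carry 5% multiplicative and 1-count additive
Gaussian noise around a baseline level U(80, 120) with smooth spatial
variation; after the 10-frame window averaging, ΔF/F noise is σ ≈ 0.022, so
the 0.15 threshold rejects >99.9% of baseline pixels. Geometry: 128×128
pixels at 4 µm/pixel (the pixel size is unpublished; this covers the
500 µm pitch neighborhood).

The generator emulates the *statistics the loop consumes* — shape
descriptors over (a, t), thresholds, heterogeneity, noise — not retinal
biophysics: there is no cable model, no discrete soma mosaic, no
degeneration, and the single-ellipse footprint is an engineering surrogate
for the soma-blob-plus-axonal-streak morphology. A green loop test
establishes that the algorithm recovers what this family states, not that
real retina behaves this way.

Two observation paths exist: the faithful path renders full frame stacks
and analyzes them through the imaging module; a fast "surface" path reads
the latent values plus calibrated measurement noise (5% relative on area,
0.02 on eccentricity — the empirical round-trip error of the full path).
Their equivalence is itself tested; ensemble evaluations use the fast path
to stay within CPU budgets.

## Surrogates and objective

Per region, two networks with one hidden layer of 10 tanh units and a
linear output map scaled (a, t) ∈ [0, 1]² to normalized activation area and
eccentricity. Trials without a calcium response are excluded; areas are
normalized by the region's maximum observed area so far, and the electrode
area constant C is expressed in the same units (recomputed each iteration
as the maximum grows). Rows split into train/validation/test within the
60–80 / 10–20 / 10–20% bands (3/1/1 at five rows; below five rows the fit
degenerates to train-on-all).

Training is damped **Levenberg–Marquardt** (`scipy.optimize.least_squares`,
analytic Jacobian) with weight decay 5e-4 appended as residuals. The decay
serves two purposes: it keeps the 41-parameter fit well-posed when trials
number fewer than weights, and it suppresses tanh oscillation in the
sub-threshold amplitude band, which carries no training points — unanchored
wiggles there create spurious local minima at the search's starting corner.
Three random restarts are drawn per net and the fit with the lowest
validation MSE is kept (the validation split's role; scipy's LM exposes no
per-iteration callback for classical early stopping); held-out test MSE is
reported. Fits are deterministic for a fixed seed.

The objective is f(a, t) = |A(a, t) − C| + E(a, t): zero for a round
response exactly covering the electrode. Eccentricity predictions are
clipped to [0, 1] as physical values. Surrogates are retrained from scratch
each iteration (the simplest reading of the published flow; warm-starting
is a possible refinement).

## Optimizer

`scipy.optimize.minimize(method="trust-constr")` — an interior-point
trust-region method with line-search globalization — over the unit-scaled
box, starting from the minimum corner (lowest amplitude and type),
step tolerance 1e-4 in scaled coordinates, iteration cap 500. Gradients of
the 2-10-1 nets are computed analytically.

The |A − C| term is nonsmooth along the A = C valley, where quasi-Newton
steps collapse and the solver can stall far from the minimum. When the
objective's structure is available the search therefore solves the exact
epigraph form

min s + E(a, t)  s.t. −s ≤ A(a, t) − C ≤ s,  (a, t) ∈ box, s ≥ 0,

the standard interior-point treatment of an absolute value; for generic
callables the plain nonsmooth path is used. The reported result is the best
accepted iterate, so f(x\*) ≤ f(x₀) always holds; recorded iterates are the
improving subsequence (rejected trust-region proposals are not moves). The
single start replicates the experimental protocol; a multi-start option
exists behind a flag, off by default. A single-start local search can still
end in a local minimum — accepted behavior, quantified by the oracle test
against the dense-grid minimum (2 µA × 1 type resolution).

## Classifier

The intended architecture is a small CNN (three 3×3×128 conv/ReLU/max-pool
blocks, then four 128-node dense layers, softmax over 5 classes). No deep
learning backend is available in the supported environment, so the trained
classifier is a scikit-learn MLP on flattened 64×64 ΔF/F images with the
same dense block and training protocol (Adam, learning rate 0.001,
cross-entropy, L2 λ = 0.0007, batch 32, 25 epochs, 90–10 train–test then
90–10 train–validation with best-validation weight restoration); dropout is
recorded in the config but unsupported by the backend. The behavioral
contract — per-class recall ≥ 0.90 on held-out synthetic images and
agreement with the rule labeler — is what the tests assert.

The training corpus is generated, not curated: balanced over the 5 classes,
with (area, eccentricity) drawn inside per-class bands that keep a margin
from the decision boundaries (ecc ≤ 0.40 or ≥ 0.60; area ≤ 1.7× or ≥ 2.4×
electrode area). This mirrors the manual relabeling of borderline images
into visually distinguishable categories; every label is recomputed by the
rule labeler on the rendered image, so labels stay consistent even when a
large footprint clips the field of view. Augmentation (orthogonal
rotations, flips, Gaussian and salt-and-pepper noise) applies to classes
1–3 only, the classes that needed balancing in practice.

## Closed loop

Schedule 5, 10, 15, 20, 46 trials: iterations sample 1, 2, 3, 4 amplitudes
per type without replacement; the final iteration is the full grid. Each
iteration resamples fresh (information from earlier batches is deliberately
not reused, matching the protocol; a cumulative mode is a flagged option).
The delivered optimum's class decides stopping (target class 1 by
default); when the schedule exhausts, the best-classed delivered response
is reported. First-iteration sampling uses the grid window rather than the
wider 20–140 µA range quoted for it, keeping every sample deliverable.

**Best attainable class** of a region is the most desirable class (order
1 > 2 > 3 > 4 > 0) over its full grid, evaluated on the noiseless latent
surfaces. The ensemble evaluation scores, per trial budget k ∈ {5, 10, 15,
20}, the probability that the best attainable class has been *observed* —
among sampled training stimuli or delivered optima, the same
group-of-results convention the random control is scored with. The control
draws k grid points uniformly without replacement, so its success
probability has the hypergeometric closed form 1 − C(46−m, k)/C(46, k)
when m grid points attain the best class; the Monte-Carlo control is
checked against this closed form.

## Numerical conventions and degenerate inputs

* Frame windows are half-open; frame counts must cover both averaging
  windows or the recording is rejected.
* Deliverable rounding: nearest type index first, then nearest integer µA
  divisible by the chosen ratio, clamped to that ratio's window; idempotent.
* Fewer than 3 responsive trials → `InsufficientDataError`; the loop logs
  the iteration and proceeds to the larger sample (an all-subthreshold
  region completes with class 0 and never trains a surrogate).
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); run logs are bit-reproducible from their
  seed triple.

## Known limitations

* In vitro headline numbers (per-region MSE tables, CNN accuracies on the
  real image corpus, trials-to-convergence statistics) are not reproduced:
  the recordings behind them are unavailable, and the synthetic world is
  not a calibrated model of them.
* The latent surface family is monotone and smooth; real regions can show
  non-monotone class sequences along amplitude. The loop's measured
  advantage over random sampling is therefore an upper bound on how much
  structure the surrogates can exploit.
* The classifier substitutes an MLP for the convolutional front end; on
  translation-heavy or texture-rich real images a CNN would be expected to
  generalize better.
* Hardware control, frequency/pulse-width sweeps, multi-electrode
  interactions, and human-fitting workflows are out of scope.
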