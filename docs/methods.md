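# Methods

This note documents the models, defaults and design decisions behind
`ceustic`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Contrast kinetics model

Tissue enhancement after a microbubble bolus is modelled with the
gamma-variate curve, the standard first-pass form in contrast imaging:

    I(t) = b + A · u^α · exp(α(1 − u)),   u = (t − t0) / tp,  t > t0
    I(t) = b                              otherwise

with baseline `b` (a.u.), amplitude `A` (a.u.), arrival time `t0` (s after
injection), time-to-peak-from-arrival `tp` (s) and dimensionless shape `α`.
The normalization makes the curve attain its maximum `b + A` exactly at
`t = t0 + tp`, which gives closed-form oracles for TTP and PI; the area of
the baseline-corrected curve on `[0, T]` has the closed form
`A·tp·e^α·γ(α+1, α·u_T)/α^(α+1)` (lower incomplete gamma), implemented in
`phantom.gamma_variate_auc` and used as the AUC oracle.

Default tissue classes (chosen once to express the qualitative clinical
picture — cancer hypoenhanced in all phases with delayed wash-in,
pancreatitis iso/hyperenhanced, necrosis non-enhancing — and not revisited):

| class        | A (a.u.) | t0 (s) | tp (s) | α   | b (a.u.) |
|--------------|----------|--------|--------|-----|----------|
| parenchyma   | 100      | 10     | 15     | 1.5 | 5        |
| cancerous    | 50       | 10     | 22.5   | 1.5 | 5        |
| inflammatory | 115      | 10     | 15     | 1.5 | 5        |
| necrotic     | 0        | 10     | 15     | 1.5 | 5        |

The malignant effect sizes (amplitude ratio 0.5, time-to-peak ratio 1.5
versus parenchyma) are configuration, not clinical claims; no quantitative
enhancement ratios exist to calibrate against, so they were set to make the
synthetic task non-trivial but learnable. `α = 1.5` gives a realistic slow
venous washout (parenchyma still ≈ 10% enhanced at 90 s) rather than a
complete return to baseline.

Timing defaults follow the clinical protocol: injection at t = 0,
parenchymal arrival at 10 s (start of the arterial phase, 10–30 s), venous
phase 30–90 s, recording 90 s at 5 frames/s.

## Phantom rendering, speckle and motion

A phantom frame is the per-class bolus intensity times a **static**
multiplicative speckle field (gamma-distributed, mean 1, dispersion
`sigma_speckle`, default 0.1), clipped to [0, 255]. Speckle is drawn once
per video because ultrasound speckle is tissue-locked: it moves with the
anatomy rather than re-randomizing every frame. This matters for
stabilization (frame-to-frame texture must be trackable) and is the main
deliberate simplification — the phantom has no point-spread function,
attenuation, shadowing, nonlinear microbubble response or out-of-plane
motion. Passing tests therefore demonstrate correctness of the analysis
chain under known kinetics and rigid motion, not performance on clinical
video.

Breathing/heartbeat motion is applied as a cumulative rigid trajectory
(translation random walk with per-frame σ, optional rotation, or an
explicit trajectory such as a sinusoid), warping each original frame once
(bilinear, edge-replicated) and returning the ground-truth transforms for
oracle tests.

The cohort generator varies mass geometry (±15% axes, ±6 px center) and
kinetics (lognormal multipliers, 10% on amplitude, 5% on tp) between
masses so the classification task is not degenerate.

## Stabilization

Classical feature-point pipeline, all on scikit-image primitives:

- **Corners**: Shi–Tomasi (minimum-eigenvalue) response; points must reach
  `quality` (default 0.01) of the maximum response, are greedily suppressed
  to `min_distance` (8 px) in response order with ties broken by (row, col),
  and are capped at `max_features` (200).
- **Tracking**: a coarse global translation from phase correlation is
  removed first, then iterative Lucas–Kanade (iLK) dense flow supplies the
  residual per-point displacement. The coarse-to-fine step exists because a
  random-walk jitter step can exceed the local flow window. Points whose
  backward-tracked position misses the start by more than τ_fb = 1.0 px are
  dropped.
- **Affine fit**: RANSAC (threshold 1.0 px, 200 trials, fixed rng) with a
  least-squares refit on the inliers; plain least squares with < 4 matches.
- **Fallback**: frames where fewer than 3 corners track (e.g. frames
  dominated by border replication after large drift) fall back to the pure
  phase-correlation translation; constant frames fall back to identity.
  Stabilization never aborts mid-video.
- **Smoothing**: the cumulative trajectory is decomposed into translation /
  rotation / scale / shear (smoothing raw matrix entries can produce
  degenerate transforms), each parameter is moving-averaged over an odd
  window (default 15 frames = 3 s, breathing-period scale; the window
  shrinks at the edges), and the smoothed trajectory is re-anchored so the
  first frame stays unwarped. Frame k is then warped by
  `smoothed_k ∘ cumulative_k⁻¹`.

A centered moving average of width W reduces the frame-to-frame increments
of a translation random walk by ≈ 1/√W, so the smoothing window bounds the
achievable jitter suppression: W = 15 leaves ≈ 26% of the raw increment,
W = 61 ≈ 13%. The jitter-reduction experiment in
`experiments.stabilization_experiment` therefore uses W = 61 (12 s) — it
contains no intentional pan that a long window could distort — while the
pipeline default stays at 15 to preserve deliberate probe motion.
Stabilization quality is audited with phase-correlation RMS frame-to-frame
displacement, independent of the tracking pipeline.

## Segmentation baseline and post-filters

The deep segmentation network of a deployed system is deliberately out of
scope (its value is in trained weights on clinical data); the module fixes
the interface, the post-filters and the IoU protocol so any segmenter plugs
in. Every candidate mask passes the same two component filters: confidence
≥ 0.50 kept, area > 20 px kept (the two commute since both are per-component
predicates). The largest surviving component is designated ROI 1.

The included baseline exploits hypoenhancement: it thresholds the temporal
mean enhancement image at `threshold_ratio` (default 0.85) times a
parenchymal reference level (median over ROI 2 when supplied, else the
image median), applies morphological closing (disk radius 2), and scores
each component's confidence as the fraction of its pixels below threshold
before closing. The averaging window defaults to the full post-arrival
window [10, 90] s rather than the venous window alone: with the default
effect sizes, a slower-washing mass has nearly parenchymal venous-phase
mean intensity, while cancer's hypoenhancement "in all phases" is strongest
around the parenchymal peak — the full window captures it. The window is a
parameter for users who want a phase-restricted variant.

IoU is |A∩B|/|A∪B| with two empty masks defined as 0 (warned); evaluation
reports mean IoU and the fraction of pairs with IoU ≥ threshold (0.50,
closed boundary: exactly-at-threshold counts as success).

## TIC extraction and features

ROI 1 is tiled with s×s cells (default s = 32 px clinically-sized frames,
s = 16 in the compact experiments) anchored at the mask bounding-box
corner; a cell is kept when ≥ 50% of its s² pixels lie inside ROI 1, and
its TIC is the mean over exactly those interior pixels (this makes
pixel-count-weighted cell means conserve the whole-ROI mean).

Preprocessing subtracts the baseline (mean intensity over a pre-enhancement
window; default [−5, 0] s relative to injection, i.e. pre-contrast frames
when the recording starts before injection — phantom runs that start at
injection use [0, 5] s, which is still pre-arrival) and applies an optional
centered moving average, clipping at 0 from below.

Features on [0, T_end] (default T_end = 90 s, configurable down to 60 s):
PI is the discrete maximum, TTP its time (first occurrence on ties —
deterministic discrete argmax), AUC the trapezoidal integral, PD =
PI_mass − PI_parenchyma (mass-minus-parenchyma sign convention: negative
for hypoenhanced cancer), RPD = PD / PI_parenchyma. TTP is measured from
injection, not from contrast arrival. RPD's denominator is genuinely
ambiguous in the field ("ratio of the peak difference" admits
PD/PI_parenchyma, PD/PI_mass, or a peak ratio); PD/PI_parenchyma is
implemented and the choice is isolated in `tic.tic_features`. When the
parenchymal peak is zero RPD is returned as NaN (flagged missing, never
infinity), and such rows are dropped (training) or imputed to 0 with a
warning (prediction).

## Classification and aggregation

A random forest (500 trees, 2 ≈ √5 features per split, unlimited depth,
seeded) maps each five-vector to a malignancy probability. Subregions
inherit their mass-level label during training — per-subregion pathology
does not exist, a documented source of label noise. At prediction time,
cells with PI below the necrosis threshold (default 5% of the parenchymal
PI; "no enhancement" is qualitative, so a small relative floor is used) are
set aside as necrosis and excluded. The mass-level call is the unweighted
mean confidence over enhancing cells (a pixel-count-weighted variant exists
behind a flag), thresholded at 0.50; a confidence of exactly 0.50 is called
malignant — the boundary's strictness is a convention, documented and
isolated in `classifier.CONFIDENCE_CUT`.

The train/test split is stratified 8:2 at mass level with
`floor(0.8·n)` per class going to training; a singleton class goes to
training with a warning.

## Thermogram and FNA target

Cells are tinted red (220, 20, 60) / blue (30, 100, 220) / gray
(128, 128, 128) for cancerous / noncancerous / necrosis, alpha-blended onto
the display frame; colors are configurable. The FNA target is the centroid
of the largest 4-connected block of cancerous cells — ties broken by higher
mean confidence, then by the top-left-most cell — snapped to the nearest
member-cell center when an irregular component's centroid falls outside its
own cells, so the target always lies in cancerous tissue. Targeting the
largest malignant block is this module's main interpretive decision; a
clinical system might equally leave the final choice to the endoscopist.

## Diagnostic and trial statistics

Standard 2×2 metrics with malignant as positive; undefined ratios (zero
denominator) are NaN, never an exception. For a single-threshold binary
classifier the ROC curve has one interior vertex, so AUC =
(sensitivity + specificity)/2; that identity is what `diagnostic_metrics`
reports, and it coincides with the rank-based AUC of the binary calls.
Continuous-score AUC is the Mann–Whitney probability with ties counted ½.
The 2×2 χ² test defaults to the uncorrected Pearson statistic
`N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))` (Yates available behind a flag); the
two-sample t test is the classic pooled-variance Student form computed from
summary statistics. Percentages are presented to one decimal and AUC to
three; all computation is unrounded.

## Experiment sizes and numerical choices

The reference experiments (`ceustic.experiments`, shared by the acceptance
tests and `scripts/acceptance.py`) use compact phantoms chosen as the
smallest sizes that exercise every code path: 80×80 px cohort masses
(~4–7 grid cells each, 200 masses, static speckle σ = 0.1), a 160×160
stabilization field (120 frames, random-walk σ = 3 px/frame — the field
keeps the ~σ√T accumulated excursion trackable), and a 64×64 noiseless
phantom for the TIC oracle (451 frames, 90 s at 5 fps). Warps are bilinear
with edge replication; trajectory rotation is unwrapped before averaging;
RANSAC uses a fixed rng so stabilization is deterministic given the video.

## Known limitations

- The phantom's speckle and kinetics are first-order approximations; no
  acoustic simulation, no out-of-plane motion, no vessel structures.
- The baseline segmenter presumes a hypoenhanced mass; an iso-enhanced
  inflammatory mass is invisible to it by construction (ROI 1 must then be
  supplied externally, as in clinical use where a trained network or the
  endoscopist provides it).
- Subregion labels inherit the mass label; a heterogeneous benign mass with
  focal malignancy is outside the synthetic task.
- Affine stabilization cannot represent non-rigid deformation of the
  pancreas; residual motion enters the TICs as noise.
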