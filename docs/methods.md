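# Methods

This note records the models, estimators, numerical choices and known
limitations behind `dsacolor`, in the order the pipeline runs.

## Input model and conventions

A DSA acquisition is a stack of `T ≥ 2` equally spaced grayscale frames;
frame `k` is assigned the time `k/fps` with `fps` defaulting to 6 frames/s,
the typical low-dose cine rate. Contrast injection is equated with
acquisition start (frame 0): injection timing is not recorded in image
data, so every "time from injection" parameter is really time from the
first frame. All intensities are converted to float64 on load.

**Polarity.** Downstream definitions assume contrast *raises* intensity,
while raw angiograms often encode iodine dark. On load, each pixel's
largest-magnitude signed deviation from frame 0 is computed; if the mean
deviation over the 1% most-changing pixels is negative, the stack is
inverted (`I ← max − I`) and the flag recorded. Using the per-pixel
extremal deviation rather than the literal last frames makes the sign
estimate robust to boluses that have fully washed out by the end of the
acquisition.

## Preprocessing

Noise suppression is an isotropic spatial Gaussian (default σ = 1 px,
reflect padding, each frame independently; σ = 0 disables). Segmentation
is deliberately simple and deterministic: the peak-enhancement image
`E = max_t I_s − min_t I_s` of the smoothed stack is thresholded by Otsu's
method, opened with a 3×3 structuring element, and components smaller than
16 px are dropped. Contrast-touched pixels (vessel *and* extravasation)
enhance strongly; background pixels only fluctuate with noise, so `E` is
strongly bimodal. The procedure is invariant to adding a spatially uniform
constant to every frame. Whether a clinical deployment would prefer manual
or vesselness-based segmentation is an open question; this choice is the
package's own, made for determinism and parameter economy.

## Bolus-model fitting

The per-pixel TIC model is
`I(t) = a0 + a1·e^(−a2·t)·σ(a3·(t − t0))` with `σ` the logistic sigmoid —
an increment `a1` switched on around the transition time `t0` at steepness
`a3` and decayed at rate `a2`. The sigmoid is evaluated with
`scipy.special.expit`, so arbitrarily large `a3` cannot overflow.

Estimation is two-stage, per pixel, order-independent:

1. **Transition and baseline.** `t0` is the time of the largest positive
   frame-to-frame difference. A transition counts as detected only when
   that difference exceeds 5× the median absolute deviation of all the
   pixel's frame differences — a robust noise floor at 6 fps frame counts.
   The baseline `a0` averages the frames *before wash-in onset*: from the
   maximum-difference frame, the rise run is traced backwards while
   differences stay above 5% of the maximum, and the frames preceding the
   run are averaged. Averaging all frames up to the steepest frame instead
   would drag the baseline upward for gradual wash-ins (the curve rises for
   several frames before its steepest frame) and bias every fitted
   parameter; the onset-aware rule removes that bias while agreeing exactly
   with the naive rule on step-like series.
2. **Amplitude and rates.** `(a1, a2, a3)` minimize the residual sum of
   squares with `(t0, a0)` fixed, by bounded trust-region least squares:
   bounds `a1 ∈ [0, 10·range]`, `a2, a3 ∈ [0, 50] /s`; start
   `(range, 0.1, 2)`; tolerances 1e-8; iteration cap ≈ 200. Optimizer
   failure is reported as `converged=False` (the pixel is excluded from
   model-based maps), never as an exception. A flat series short-circuits
   to `a1 = 0`.

**Identifiability at 6 fps.** With ~0.17 s between frames, wash-in slopes
`a3 ≲ 3 /s` entangle with the baseline estimate and cannot be recovered to
5%; slopes up to the 50 /s bound remain identifiable from the frames
straddling `t0`. The recovery tests therefore span `a1 ∈ {30, 95, 300}`
image units, `a2 ∈ {0.05, 0.16, 0.5} /s` (washout half-life ~1.4–14 s) and
`a3 ∈ {5, 15, 50} /s` — one decade each, centered on regimes realistic for
contrast angiography at this frame rate.

## Parameter maps

TOA, TTP and transit are read from the (smoothed) series directly; AUC and
flow from the fitted curve — the integral and derivative of a noisy raw
series would be noise-dominated, while threshold crossings and argmax are
already robust. The "increase greater than 15%" trigger is interpreted as
15% of the per-pixel enhancement *range* (peak − baseline), not of the raw
baseline: subtracted backgrounds sit near zero, where a ratio-to-baseline
threshold is numerically unstable, and the range-relative form is invariant
to constant offsets. Ties at the peak break to the earliest frame. The
analysis window is a single global `(t_start, t_end)` defaulting to the
full sequence. AUC uses the trapezoid rule at frame times; flow evaluates
the analytic derivative
`dI/dt = a1·e^(−a2·t)·(a3·σ(1−σ) − a2·σ)` on a grid at 10× the frame rate.
"Flow rate" as wash-in slope is a proxy choice; a front-velocity definition
(spatial gradient of TOA along a centerline) would also be defensible but
is not implemented.

## Pseudo-coloring

Maps are normalized affinely between their 1st and 99th valid-pixel
percentiles (robust to single-pixel fit outliers; a constant map renders
at 0.5 by convention), then colored by piecewise-linear interpolation in
RGB between LUT stops. The default `toa-ryb` scale is red (255,0,0) at 0,
yellow (255,255,0) at 0.5, blue (0,0,255) at 1 — earliest arrival red,
latest blue. The same LUT is reused for the other four parameters by
default and is overridable. Invalid pixels render black, matching the dark
background of subtracted angiograms. Rendering is purely functional:
identical inputs give bit-identical PNGs.

## Phantom generator

The phantom emulates a bench bleeding rig: a thin tube (polyline path,
radius ~3 px) carrying a bolus front at constant speed, with an optional
breakpoint part-way along the path where contrast extravasates into a
roughly circular blob. Pixel arrival time is arc distance / front speed
(tube) or breakpoint time + radial distance / a slow spread speed (blob).
After arrival, enhancement follows
`A·(1 − e^(−r·τ))·e^(−w·τ)` with fill rate `r` and washout rate `w`.
Defaults: 128×128, 60 frames at 6 fps, front speed 40 px/s, amplitude 100,
fill rate 20 /s (the front saturates a pixel within about one frame —
a sharp bolus front), washout 0.15 /s; the leak fills slowly (0.8 /s) and
clears much slower than the vessel washes out (0.05 /s < 0.15 /s), which
is the persistence signature of active bleeding and is enforced when the
phantom parameters are validated. Noise is i.i.d. Gaussian (default σ = 2 image units) from a
seeded generator: identical spec ⇒ bit-identical output.

The battery generator draws randomized cases (front speed 25–60 px/s,
amplitude 60–140, radius 2–4 px, noise 1–3, breakpoint at 40–70% of the
path) with a configurable fraction of leaky cases, mirroring a 27-run
bench protocol at desk scale.

**What the phantom does not model:** patient/organ motion, x-ray quantum
noise and scatter, vessel trees with branching or overlap, recirculation,
and acquisition physics (dose, injection pressure). Passing phantom tests
therefore demonstrates correctness of the estimators on clean bolus
kinematics, not robustness to clinical artifacts.

## Reader-score statistics

Scores are 1–5 consensus confidence ratings (1 definitely no bleeding … 5
definite bleeding), one pair per case (DSA alone, DSA + color).
Reinforcement counting takes the indeterminate set (score < 5 toward
bleeding, > 1 toward no bleeding) and partitions it into reinforced /
downgraded / unchanged by the sign of the score change. The Wilcoxon
signed-rank test discards zero differences (classical convention, matching
common SPSS defaults; Pratt's method is not used), average-ranks tied
magnitudes, and computes the two-sided p exactly — full enumeration of the
2^n sign assignments, which accommodates average ranks — for up to 12
nonzero differences, switching to the tie- and continuity-corrected normal
approximation beyond. The packaged fixtures encode published aggregate
transitions (101 bleeding cases, 34 non-bleeding, 22 of 27 bench runs; the
5 unreported bench runs are excluded); per-case orderings within a
transition block are not published, which does not affect counts or the
test. Exact published p-values from other software are not reproduced —
only significance at the 0.05 level is asserted.

## Problem sizes and determinism

Tests and the acceptance script run phantoms at 128×128×60 (headline
arrival-time accuracy), 96×96×48 (battery) and 64×64×36 (per-pixel fitting
end-to-end), sizes at which the whole suite completes in seconds while
leaving hundreds of vessel pixels per case. All randomness flows through
`numpy.random.default_rng` with explicit seeds; the CLI records its full
configuration (seed included) in a JSON echo sufficient to reproduce any
run.
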