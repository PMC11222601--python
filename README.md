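# dsacolor

Color-coded parametric imaging for digital subtraction angiography (DSA).

Active bleeding is easy to miss on a gray-scale DSA cine loop: the
extravasation is faint, transient, and hidden among overlapping vessels.
`dsacolor` condenses an entire 2D+time DSA sequence into single parametric
images — most usefully a **time-of-arrival (TOA)** map — and renders them
through a red→yellow→blue color scale so that contrast that arrives early
(arteries, and the jet feeding a bleed) stands out in red against
late-filling structures in blue. The package is aimed at interventional
radiology researchers and at anyone building or validating perfusion-display
pipelines; it ships a synthetic phantom generator with exact ground truth,
so every stage can be tested without patient data.

## Method

For every pixel inside the segmented vasculature, the time–intensity curve
(TIC) across the frame stack is fitted with a bolus model

```
I(t) = a0 + a1 · e^(−a2·t) / (1 + e^(−a3·(t − t0)))
```

where `a0` is the baseline intensity before contrast arrives, `a1` the
contrast intensity increment, `a2` (1/s) the rate at which the peak
intensity is halved (washout), `a3` (1/s) the rising slope of the wash-in,
and `t0` (s) the transition point of the perfusion process. Fitting is
two-stage: `t0` and `a0` come from the frame-to-frame difference signal
(the largest positive inter-frame jump marks the transition; the frames
before wash-in onset average to the baseline), then `(a1, a2, a3)` are
estimated by bounded least squares with `(t0, a0)` held fixed.

Five parameters are then mapped per pixel over a selectable time window:

| parameter | definition | computed from |
|---|---|---|
| TOA | first frame exceeding baseline + 15% of the enhancement range | raw (smoothed) series |
| TTP | first frame attaining the maximum | raw series |
| Transit | 15% rise trigger → post-peak 15% fall | raw series |
| AUC | ∫ max(I(t) − a0, 0) dt (trapezoid at frame times) | fitted curve |
| Flow | max dI/dt (wash-in slope) | fitted curve |

Each map is percentile-normalized and passed through a color lookup table;
the default `toa-ryb` scale anchors red at the earliest arrival, yellow at
the midpoint and blue at the latest.

The `reader_eval` module adds the statistics used to evaluate such displays
clinically: paired 1–5 diagnostic-confidence scores (DSA alone vs DSA +
color), reinforcement counting over the initially indeterminate cases, and
a two-sided Wilcoxon signed-rank test (exact by enumeration up to 12
nonzero differences, tie-corrected normal approximation beyond).

## Worked example

```python
import numpy as np
import dsacolor as d

truth = d.generate_phantom(d.PhantomSpec(seed=0))   # 128x128, 60 frames @ 6 fps
seq      = truth.sequence
smoothed = d.gaussian_lowpass(seq, 1.0)
mask     = d.segment_vessels(seq)
maps     = d.build_param_maps(smoothed, mask, ["toa", "ttp", "auc"])

toa = maps["toa"]
err = np.abs(toa.values - truth.toa_true)
both = truth.vessel_mask & toa.valid
print(f"TOA map: {toa.valid.sum()} valid px, "
      f"range {toa.values[toa.valid].min():.2f}-{toa.values[toa.valid].max():.2f} s")
print(f"median |TOA error|: {np.median(err[both]):.3f} s")

norm, valid = d.normalize_map(toa)
rgb = d.apply_lut(norm, valid, d.LUTS["toa-ryb"])   # (128, 128, 3) uint8
```

prints

```
TOA map: 862 valid px, range 0.17-3.33 s
median |TOA error|: 0.083 s
```

i.e. the pipeline segments the phantom's tube and leak blob (862 pixels),
recovers arrival times spanning the bolus transit of the tube, and its
median arrival-time error (0.083 s) is half the 0.167 s frame interval —
the best any frame-quantized estimate can do on average. The `rgb` image
shows the injection end red, the far end blue, and the extravasation blob
conspicuously late (blue) relative to the tube segment it sits on.

The same pipeline runs from the shell:

```sh
dsacolor phantom --out ph --seed 7
dsacolor process --input ph/sequence.tif --param all --out run
dsacolor evaluate --scores my_scores.csv
dsacolor colorize --map run/map_toa.tif --lut toa-ryb --out toa.png
```

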