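# standcount

Seedling stand counting and mechanical-seeding performance evaluation
from ultrahigh-resolution UAV RGB imagery.

## The problem

Direct-seeded crops with small, overlapping seedlings — rapeseed
(*Brassica napus* L.) being the motivating case — cannot be counted by
simply counting green blobs: one connected vegetation object frequently
holds several plants (mostly 1–3, occasionally many more). This package
implements an object-based pipeline for plot imagery at ~0.18 cm ground
sampling distance:

1. **Segmentation** — a color vegetation index (default ExG−ExR
   = 3G − 2.4R − B; also ExG, ExR, NGRDI, GLI) is thresholded per plot
   with Otsu's method; objects smaller than 1.16 cm² (≈36 px) are
   removed as weeds, and fragments no more than 1.0 cm apart are merged.
2. **Shape features** — fifteen descriptors F1–F15 per object: minimum
   enclosing rectangle geometry (perimeter, area, area–perimeter ratio,
   length–width ratio), pixel-count and border-length measures, and
   moment-based form factors (shape index, density, asymmetry,
   rectangular and elliptic fit, roundness, compactness).
3. **Count model** — per-object plant count ŷ is affine in selected
   features. Selection is a collinearity screen (of any pair with
   |r| > 0.8, keep the member better correlated with the count) followed
   by stepwise multiple regression (entry p ≤ 0.05, removal p ≥ 0.10).
   Three fitted field models ship as built-ins, all of the form
   ŷ = a·F4 + b·F12 + c·F15 + d (length–width ratio, density, border
   length). Plot totals are Σŷ rounded to integer; accuracy is scored by
   the signed relative error Es and the mean absolute error
   MAE = mean|Es| over validation subsets.
4. **Row analysis** — objects are polygonised, buffered, filtered by the
   area-median, reduced to points, clustered into the known number of
   rows, connected along the seeding direction and smoothed. The row
   characteristics are

   - CV_rs = SD_rs / X̄_rs · 100 (coefficient of variation of adjacent-row
     spacings x_i, divisor N−1),
   - E_rs = (X̄_rs − T)/T · 100 against the seeder's theoretical pitch T,
   - CV_su = SD_su / X̄_su · 100 over per-row estimated seedling totals
     u_i (objects within 8.0 cm of a line; divisor N).

5. **Synthetic fields** — a georeferenced generator renders plots with
   programmed row pitch, plant clusters, weeds and soil texture, with
   complete ground truth (plant positions, per-cluster multiplicities,
   true row centers, vegetation mask), so every stage is testable
   end-to-end.

## Worked example

```python
import numpy as np
import pandas as pd
from standcount import (generate, stage_presets, segment_image, features_table,
                        predict_counts, validation_metrics)
from standcount.count_model import (correlation_matrix, preselect, stepwise_fit,
                                    round_half_away)
from standcount.synthetic_field import object_truth_counts
from standcount import row_analysis as ra

# 1. render a plot with known truth
img, truth = generate(stage_presets(2), seed=7)
objs, thr, mask = segment_image(img)          # ExG-ExR + Otsu + cleanup

# 2. train a count model on two independent plots
frames = []
for seed in (101, 102):
    im, tr = generate(stage_presets(2), seed=seed)
    ob, _, _ = segment_image(im)
    ft = features_table(ob)
    counts, _ = object_truth_counts(ob, tr)
    ft["y"] = [counts[l] for l in ob.labels]
    frames.append(ft)
train = pd.concat(frames, ignore_index=True)
model = stepwise_fit(train, candidates=preselect(correlation_matrix(train)))

# 3. estimate the held-out plot's stand count and row characteristics
feats = features_table(objs)
yhat = predict_counts(model, feats)
total = round_half_away(float(yhat.sum()))
val = validation_metrics([truth.total_plants], [total])
pts = ra.build_row_points(objs)
labels = ra.assign_row_labels(pts, n_rows=8, theoretical_spacing=20.0)
lines = ra.connect_and_smooth(pts, labels)
sp = ra.row_spacing_stats(lines, 20.0)
cents = np.array([objs.centroid_world(l) for l in objs.labels])
su = ra.seedling_uniformity(cents, yhat, lines)

print(f"plot: {img.shape[1]}x{img.shape[0]} px, {truth.total_plants} plants")
print(f"Otsu threshold: {thr:.1f}   objects: {len(objs)}")
print(f"model: {model.features}, R2 = {model.stats['r2']:.3f}")
print(f"estimated total: {total}   measured: {truth.total_plants}   "
      f"Es = {val.es_percent[0]:+.2f}%")
print(f"mean row spacing: {sp.mean_spacing:.2f} cm   CV_rs = {sp.cv_rs:.2f}%   "
      f"E_rs = {sp.e_rs:+.2f}%   CV_su = {su.cv_su:.2f}%")
```

Output of this run:

```
plot: 1111x1389 px, 382 plants
Otsu threshold: 35.5   objects: 167
model: ['F6', 'F9', 'F13'], R2 = 0.867
estimated total: 380   measured: 382   Es = -0.52%
mean row spacing: 19.79 cm   CV_rs = 5.33%   E_rs = -1.06%   CV_su = 18.42%
```

Reading it: 382 plants were rendered; segmentation found 167 connected
objects (each holding ~2.3 plants on average), the model fitted on two
training plots estimated 380 plants (Es = −0.52 %), and the detected
rows sit 19.79 cm apart on average against the programmed 20 cm pitch
(E_rs = −1.06 %) with a 5.33 % spacing CV. CV_su summarises how evenly
the estimated plants are distributed over the eight rows.

The same flow is available from a shell via the `standcount` CLI
(`simulate`, `segment`, `eval-seg`, `features`, `fit`, `count`, `rows`,
`run-all`); `standcount run-all --image plot.png --gsd 0.18` prints a
single JSON report.

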