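# phasesnake

Segmentation and tracking of a single cell's boundary in phase-contrast
microscopy image sequences, built for quantitative morphology and
motility analysis of lymphocytes and similarly sized non-dividing cells.

Phase-contrast images are hard on classical active contours: the cell
interior carries intensity "holes" that spawn spurious edges, parts of
the boundary are genuinely low-contrast, and snakes are sensitive to
their starting position. `phasesnake` addresses all three with one
pipeline:

* **MGRL feature map** — morphological gray-scale reconstruction floods
  the dark cell body into a single intensity plateau (erasing interior
  holes), a Laplacian-of-Gaussian filter (σ = 2, 13×13) with
  noise-gated zero-crossing detection extracts the boundary, and
  connected edge fragments smaller than P = 15 px are removed. The
  result is a sparse binary map, typically one closed curve on the cell
  boundary.
* **VFC external force** — the feature map is convolved with the vector
  field kernel k(x, y) = (x² + y² + ε)^(−r) · n(x, y), where n points to
  the kernel origin, so every boundary pixel attracts the contour with a
  force decaying as the 2r-th power of distance.
* **Snake** — a closed polygon evolves by the explicit update
  x_i ← x_i + γ(α·D₂x_i − β·D₄x_i + u(x_i, y_i)) with periodic finite
  differences, arc-length resampling, and step-size/oscillation guards
  (reference weights α = 2, β = 0.2, 100 iterations).
* **Initialization near the phase halo** — histogram-mode thresholding
  of the reconstruction-flattened ROI plus disk open–close puts the
  starting contour within a few pixels of the true boundary.
* **Tracking** — segmentation frame by frame, each frame initialized by
  the previous frame's final contour.

A gradient-vector-flow (GVF) snake is included as the comparison
baseline, and a synthetic generator renders phase-contrast-like cells
(halo, interior holes, low-contrast arcs, drift) with exact ground-truth
masks for evaluation by Jaccard coefficient JC = |A∩B| / |A∪B|.

## Worked example

```python
import numpy as np
from phasesnake import (Config, RectROI, SceneSpec, SequenceSpec, crop,
                        evaluate_run, make_cell_sequence, summarize, track)

# ten frames of a drifting, deforming synthetic cell with ground truth
seq = SequenceSpec(base=SceneSpec(), n_frames=10, drift=(0.7, -0.5),
                   walk_scale=0.15, seed=42)
frames, truths = make_cell_sequence(seq)

roi = RectROI(48, 48, 209, 209)           # user-selected box around the cell
result = track(frames, roi, Config(), frame_interval=0.04)

stats = evaluate_run(result, [crop(t.astype(float), roi) > 0.5 for t in truths])
print(summarize(result).head(3).round(2).to_string(index=False))
print(f"mean JC = {stats.mean:.4f}, STD = {stats.std:.4f}")
```

Output:

```
 frame  time_s  area_px2  perimeter_px  centroid_x  centroid_y  iterations  converged  reinitialized
     0    0.00   3275.03        204.85       79.94       79.76         100      False          False
     1    0.04   3255.37        204.72       80.55       79.08         100       True          False
     2    0.08   3256.40        204.52       81.27       78.59         100       True          False
mean JC = 0.9783, STD = 0.0029
```

The summary table is the per-frame morphology record (area and perimeter
in pixels, centroid in ROI coordinates, iterations used); the Jaccard
row says the tracked masks overlap the ground truth at ~0.98 on every
frame. The `converged` flag reports whether the contour displacement
fell below 0.05 px within the budget — under the reference
fixed-100-iteration setting the contour keeps polishing to the end, so
the flag is informational.

The same pipeline is available from the shell:

```
phasesnake simulate --seed 42 --out data/
phasesnake track --input data/frames.tif --roi 44,60,198,215 --out run/
phasesnake evaluate --pred run/masks --truth truth/ --out stats.csv
phasesnake segment --input data/frames.tif --frame 0 --roi 44,60,198,215 --out seg/
```

(`track` writes contour CSV, per-frame mask and overlay PNGs, a summary
CSV, and a JSON run log. For `evaluate`, note that predicted masks are
ROI-local; crop the truth masks accordingly.)

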