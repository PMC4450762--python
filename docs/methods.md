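# Methods

`phasesnake` segments and tracks the boundary of a single cell (the
motivating application is lymphocytes) in phase-contrast microscopy
sequences with a parametric active contour whose external force is a
vector field convolution (VFC) of a sparse binary feature map built from
morphological gray-scale reconstruction and a Laplacian-of-Gaussian
filter. This note records the model, the numerical choices, and what the
synthetic test bed does and does not establish.

## The model

A closed contour C(s) = [x(s), y(s)] minimizes

    E = ∫ ½(α|C'(s)|² + β|C''(s)|²) + E_ext(C(s)) ds

with elasticity weight α and rigidity weight β. The Euler–Lagrange
equations are solved by explicit gradient descent on a polygon of N
points with periodic finite differences:

    x_i^{n+1} = x_i^n + γ (α D₂x_i − β D₄x_i + u(x_i, y_i))

(and likewise for y), where D₂ and D₄ are the second and fourth central
differences divided by ds² and ds⁴ and (u, v) is the external force field
sampled bilinearly at the subpixel point.

**External force (VFC).** The field is the convolution of a feature map
f(x, y) with the vector kernel

    k(x, y) = (x² + y² + ε)^(−r) · n(x, y),

n being the unit vector toward the kernel origin. Every feature pixel
attracts the contour with a force decaying as the 2r-th power of
distance; superposition gives the field of an arbitrary map. The kernel
is truncated at the smallest radius whose omitted tail is below 1e−4 of
the peak magnitude (10–11 px for r = 2, ~100 px for r = 1); an explicitly
smaller radius is rejected rather than silently degraded.

**Feature map (reconstruction + LoG).** Phase-contrast cell interiors
carry intensity inhomogeneities ("holes") that a plain edge detector
turns into spurious attractors, and parts of the boundary can be
genuinely low-contrast. The feature map therefore combines region and
edge information:

1. *Hole filling by gray-scale reconstruction.* Reconstruction by
   dilation of the intensity complement from a border-seeded marker
   raises every regional minimum not connected to the border to its
   lowest escape saddle. Because the dark cell body is enclosed by the
   bright phase halo, the entire body floods to a single exact intensity
   plateau; interior holes vanish into it.
2. *LoG filtering.* The filled image is convolved with a discrete
   Laplacian-of-Gaussian kernel (σ = 2, 13×13, mean-corrected to zero
   sum; reflect padding here and in all convolutions).
3. *Zero crossings.* A pixel is marked when its response is positive and
   a 4-neighbour's is negative (the darker side of each crossing), giving
   one-pixel-thick curves. A crossing is kept only when the response jump
   across the pair exceeds an amplitude gate: the larger of 1% of the
   maximum absolute response and 4× the robust (MAD) scale of
   pixel-to-pixel response differences. The second term is a noise
   floor — on noisy images, sign flutter produces jumps at the scale of
   the response noise and a fraction of the maximum alone cannot separate
   the two populations.
4. *Small-component removal.* Connected edge fragments with fewer than
   P pixels (default 15, recommended range 15–20) are dropped.

The result is a binary map, typically a single closed curve hugging the
cell boundary, one to two orders of magnitude sparser than a gradient
edge map of the same ROI.

**Initialization.** The threshold is the mode of a 256-bin histogram of
the reconstruction-filled ROI: the flooded body is an exact plateau, so
it occupies a single dominant bin. Because the target is assumed centered
in the ROI, the mode is estimated on the central 60% window (in a
generously sized ROI the background would out-populate the one-bin
plateau); binarization |I − thr| ≤ tol is then applied to the full ROI.
The tolerance defaults to half the distance to the nearest other
prominent histogram mode, clipped to 5–7 intensity levels — the upper
clip keeps the band from swallowing the halo-skirt shell around the
plateau value, which would attach to the plateau and survive the
morphological clean-up. Disk open–close (radius 3) removes speckle, the
component nearest the ROI center (ties to the larger) is kept, and its
subpixel marching-squares boundary, resampled to uniform arc length,
is the initial contour. It typically lands within 1–3 px of the true
boundary, which is what keeps the 100-iteration budget sufficient.

**Tracking.** Segmentation is repeated frame by frame with a fixed ROI;
the final contour of frame k initializes frame k+1 unchanged (inter-frame
motion is assumed small relative to the force field's capture range).
A mid-sequence evolution collapse triggers one fresh re-initialization;
a second failure aborts.

## Reference parameters

| key | default | meaning |
|---|---|---|
| `alpha` | 2.0 | elasticity weight (GVF baseline uses 0.8) |
| `beta` | 0.2 | rigidity weight |
| `gamma` | 0.5 | time step (guarded, see below) |
| `iterations` | 100 | per-frame iteration budget |
| `vfc_r` | 1 | kernel decay exponent in the reference profile¹ |
| `vfc_eps` | 1e−8 | kernel regularizer |
| `log_sigma`, `log_size` | 2, 13 | LoG filter |
| `edge_sigma` | 3 | Gaussian of the traditional edge map |
| `min_component_size` | 15 | edge-fragment threshold P |
| `init_disk_radius` | 3 | open–close structuring element |
| `gvf_mu`, `gvf_iters` | 0.1, 500 | GVF regularization and diffusion steps |
| `target_spacing` | 2 px | contour point spacing |
| `tol` | 0.05 px | convergence displacement |

¹ The method description quotes r = 2 while the reference parameter
table lists r = 1; both are supported. `make_vfc_kernel` defaults to 2
(the method text); the `Config` profile mirrors the parameter table and
uses 1.

## Numerical choices

* **Parameter spacing ds = 1.** With the normalized spacing
  h = 1/(N−1) the difference terms scale as N² and N⁴, so reference
  weights of order 1 against O(1) external forces either diverge or,
  after step-size guarding, freeze the contour. Unit spacing — the
  convention of published snake implementations — makes α and β act in
  pixel units independent of the point count. The normalized spacing
  remains available (`SnakeParams.ds = None`) and is exercised by the
  update-equation oracle tests.
* **Step-size guard.** γ is halved whenever a single iteration would
  move any point by more than twice the target spacing.
* **Per-point oscillation damping.** Near the sharp VFC ridge the
  explicit update is neutrally stable: a point hops across the ridge
  indefinitely. When a point's consecutive steps oppose each other its
  step factor is halved (recovering by 5% per quiet iteration, floor
  1/64), turning the hop into convergence while travelling points keep
  the full step.
* **Fixed-iteration default.** The reference setting runs the full
  budget; the converged flag latches when the largest per-point
  displacement of an iteration falls below `tol`, and early stopping is
  optional (`stop_on_convergence`).
* **Resampling.** Every 10 iterations the polygon is redistributed at
  uniform arc length (N = perimeter / 2 px, minimum 16 points); duplicate
  consecutive points are merged, orientation is normalized to positive
  signed area.
* **Collapse detection.** Enclosed area below 4 px² raises an error
  rather than returning a degenerate contour.
* **GVF baseline.** The traditional edge map |∇(G₃ ∗ I)| is scaled to
  [0, 1], diffused by explicit gradient descent with a Lipschitz-bounded
  step, and the resulting field is normalized to unit vectors (the
  practice of the reference GVF implementation). Without that
  normalization the GVF force (~0.1) is weaker than the elasticity and
  the snake leaks steadily inward under a fixed budget — an unfairly
  crippled baseline.

## The synthetic test bed

No phase-contrast lymphocyte recordings ship with the package, so all
quantitative checks run on a generator that emulates their salient
structure: a dark
deformable body (star-convex boundary with order-2–5 Fourier harmonics)
on a brighter noisy background; a bright phase halo hugging the boundary
with a sharp inner rise (0.9 px), crest 1.5 px outside the boundary, and
a slow outer skirt (decay scale 8 px); interior dark patches, the first
placed peripherally where inhomogeneity most disturbs edge detection; one
low-contrast arc per cell (span 0.7–1.6 rad, contrast factor 0.25–0.5)
where the halo is attenuated *and* the body edge fades into the
background, so the edge there is genuinely weak for any method; and
distractor blobs kept outside the diagonal of the enclosing ROI.
Intensities are on a nominal 8-bit scale (body 60, background 130, halo
crest 200) with Gaussian noise σ = 1.8 after a 0.7 px optical blur.
Sequences add per-frame centroid drift, a random walk on the harmonic
amplitudes, and fresh per-frame noise (a fully static spec replicates one
frame exactly).

What the generator does **not** emulate: shot-noise statistics,
shade-off (the bright interior gradient of large phase objects), debris
overlapping the cell, focus drift, multiple touching cells, and halo
side-lobes. Passing the synthetic suite therefore shows the algorithm's
internal consistency and its behaviour under the modelled artifacts —
halo, interior holes, low-contrast arcs, drift — not performance on any
particular microscope's output.

On this bed, with the reference parameters: segmentation reaches a mean
Jaccard coefficient of ~0.98 (sample STD ~0.004) over 25 randomized
low-contrast cells within the 100-iteration budget, against ~0.94 for the
GVF baseline on the same fixtures with the same initialization; the
initialization alone scores ~0.95; and 30-frame drifting sequences track
with per-frame Jaccard ≥ 0.96 without re-initialization. These are the
quantities `scripts/acceptance.py` recomputes.

## Known limitations

* One target per ROI; no topology changes, splitting, or merging.
* The histogram initialization needs the halo (or some enclosing bright
  barrier): on a cell whose boundary is entirely low-contrast the
  reconstruction plateau floods away and no threshold mode exists.
* By default the fixed ROI must contain the cell for the whole sequence;
  `recenter_roi` shifts the ROI with the tracked centroid for longer
  drifts, at the cost of ROI coordinates that change per frame.
* The explicit scheme with guards is robust but not fast; the
  semi-implicit pentadiagonal solver would allow larger time steps.
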