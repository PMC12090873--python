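# Methods

## The problem

Quantitative wood anatomy measures cell and ring structure in
high-resolution thin-section images of stems. Before any per-ring
quantity can be computed, every growth ring must be delineated as one
instance: a closed annular band around the pith. Rings of arctic
shrubs make this hard in a specific way — they are concentric, often
extremely narrow, and they *wedge*: a ring can pinch to zero width
over an angular arc and reappear elsewhere. Generic instance
segmentation (box-based or proposal-based) fails on such large,
hollow, heavily overlapping objects.

`ringseg` implements an iterative, regression-based scheme tailored
to this geometry. Rings are segmented one at a time, from pith to
bark. At each step the scene is resampled onto a polar grid anchored
on the current ring boundary, and a convolutional regressor predicts,
for every angular position, the radial distance to the *next*
boundary. Because exactly one distance is predicted per angle, the
model cannot produce the classic failure mode of boundary-pixel
classifiers — multiple or broken edges in one radial column — and the
prediction is directly interpretable as a per-angle ring width. The
same framing allows a per-angle uncertainty to be learned jointly.

## Pipeline

1. **Semantic pre-segmentation.** A small encoder–decoder CNN with
   skip connections (`semantic.SegNet`) maps the ×4-downscaled RGB
   image to four sigmoid-activated binary masks: *pith*, *background*
   (non-xylem), *ring* (xylem), *boundary* (interfaces between
   consecutive rings plus the outer xylem edge). Each mask is trained
   with a binary dice loss
   `L = 1 − (Σ y·ŷ + ε)/(Σ(y+ŷ) + ε)`, ε = 1, combined as
   `0.1·L_pith + 0.01·L_background + 1.0·L_boundary + α_ring·L_ring`.
   Only three of the four classes carry a prescribed weight; the ring-class
   weight is a free parameter defaulting to the background weight
   (0.01). A config switch (`dice_conventional`) selects the usual
   2·intersection dice numerator; the default keeps the form above.

2. **Initialization.** The pith probability map is thresholded at 0.5;
   the largest connected component gives the center and, by radial ray
   marching, the initial boundary, resampled to M equally spaced
   angles. If no pith is found the caller may supply one
   (`pith_override`) — the intended mode for material the model was
   never trained on.

3. **Iteration.** Repeating until a stopping signal:
   - *Adaptive angular resolution:* `M = round(2π · mean radius)`,
     clamped to ≥ 8, keeping the arc spacing between boundary points
     at ~1 px at every radius.
   - *Ring-width estimate:* from each boundary point a ray marches
     outward in 1-px steps (after a 2-px blanking distance that skips
     the current boundary's own mass) until it hits a binarized
     boundary pixel; rays are abandoned on hitting binarized
     background or the image edge. `P = 1.5 × 95th percentile` of the
     hit distances — robust to outliers and long enough that the next
     boundary falls inside the polar window. If fewer than 20% of the
     rays hit anything, the estimate is *absent*: the bark or the
     xylem edge has been reached, and the loop stops. Because the
     boundary class is rasterized as a band of configurable width
     (3 px at the downscaled resolution), the first hit lands on the
     band's inner lip; callers compensate by the known band half-width
     so that P refers to the interface itself.
   - *Polar image:* a 6×N×M resampling (N = 256 radial rows by
     default) whose row 0 lies exactly on the current boundary and
     whose columns fan radially outward from the shared center with
     step P/N. Channels: the 3 image channels and the background and
     boundary *logits* (pre-activation), all bilinearly interpolated,
     plus the distance of each sample to the center, min–max
     normalized to [0, 1] within the polar image (per-image
     normalization keeps the channel bounded while conveying global
     scale).
   - *Radial regression:* the network below predicts per-angle
     normalized distances δ ∈ [−1, 1] (and optionally Laplace scales
     b > 0). Distances convert back through the inverse normalization
     composed with the ray step: `d_px = (δ+1)·P/2`.
   - *Advance:* the boundary moves outward by `max(d_px, 0)` — an
     inward prediction may touch but never cross its predecessor, so
     consecutive boundaries stay nested. If the mean advance falls
     below `min_advance_px` (0.1 ds px by default) the loop also
     stops; this guards against spinning at the xylem edge where the
     width estimate can stay technically present while the regressor
     correctly predicts no further ring. A hard iteration cap
     (200) guarantees termination on pathological inputs.

4. **Rendering.** Boundary polygons are scaled to full resolution
   (`full = 4·ds + 1.5`, the block-center mapping of the ×4 area
   downscale) and rasterized outside-in, each filled polygon
   overwriting the interior of the previous one, producing nested
   annuli; the pith interior maps to label 0 (configurable).

## The radial regression network

Polar images have per-sample angular sizes (M follows the ring
radius), so samples cannot be concatenated into batches; batching is
emulated by gradient accumulation (8 forward passes per optimizer
step) and all normalization is per-sample (instance norm). The
network is an encoder–decoder over the 6×N×M polar image with these
properties:

- **Circular convolutions** — all convolutions wrap around in the
  angular dimension, matching the topology of the polar space.
- **Radial-only striding** — pooling and upsampling act only on the
  radial axis. Combined with circular convolutions this makes the
  network *exactly* equivariant to angular rotation: shifting the
  input columns by s shifts the output by s, to float precision. (Any
  angular stride would break exactness for odd shifts.)
- **Dilated context block** — three parallel convolutions (1×1, and
  3×3 at angular/radial dilations 2 and 4) concatenated and projected
  to 64 filters (the reduced pyramid width), with *no* normalization
  after the block.
- **Feature bypass** — the decoder output is upsampled radially and
  concatenated with the raw polar image, so the already-computed
  semantic evidence re-enters just before the prediction.
- **Radial average pooling** — a mean over the full radial dimension
  (kernel N×1) collapses the map to 1×M; a final 1×1 convolution
  yields 1 channel (δ) or 2 channels (δ and the pre-softplus
  uncertainty).

Targets are normalized with `n(d) = (d − N/2)/(N/2)` before the loss;
training minimizes the summed absolute error `Σ_m |δ_m − n(d_m)|`
(a mean-reduction flag exists because M varies per sample, but the
sum is the default). With uncertainty enabled the loss becomes the
Laplace negative log-likelihood `Σ_m |δ_m − n(d_m)|/b_m + log b_m`,
interpreting (δ, b) as the location and scale of a Laplace
distribution; b is produced by a softplus with a floor of 10⁻³,
which prevents the log-divergence at b → 0. The per-angle standard
deviation in pixels is `σ_m = √2 · b_m · P/2`.

## Iterative unrolling

Training starts the iterative process from *every* ground-truth ring
boundary and runs at most K = 3 steps, so each ring is visited with
similar frequency. Instead of running K consecutive steps inside one
training step, the steps are unrolled over K epochs: each training
step performs a single forward pass and saves its predicted boundary
to disk; in the next epoch the loader reads that boundary and builds
the next polar image, so the record has effectively advanced one
iterative step. Every (image, ring-start) pair is duplicated K times
with staggered starting epochs, which makes each epoch a mixture of
different images *and* different iteration steps — the multiset of
(sample, step) pairs processed over any K epochs equals the naive
inner-loop schedule's. Boundary files are keyed by epoch parity, so a
boundary written in epoch e can only be read in epoch e+1 (no
read/write races). The segmentation model's outputs are computed once
and cached to disk (stale or corrupted entries are recomputed).

Details the scheme leaves open, resolved here:

- Ray columns whose target crossing does not occur within the N polar
  rows are masked out of the loss; a start whose valid-column
  fraction falls below 50% is treated as *absent* (this excludes
  outermost-ring starts without aborting on wedging arcs).
- A column whose ray begins already outside the next ring — the next
  ring wedges to zero width at that angle — has target distance 0,
  teaching the regressor to hold the boundary still on wedge arcs.
- Targets are always measured against the ground-truth mask from the
  *current* (possibly drifted) boundary: the distance to the first
  crossing out of the union of rings 1..k+1, where k is the majority
  ground-truth label just inside the boundary.
- Duplicates scheduled before their staggered start epoch train from
  their ground-truth start (a K−1-epoch transient).

## Evaluation suite

All instance metrics exclude label 0 (background and pith): rings are
the instances. Implemented from their definitions and tested against
brute-force contingency-table oracles:

- IoU; one-to-one matching at IoU > 0.5 (automatically unique);
- mAR = (2/k) Σ_i max(IoU(gt_i) − 0.5, 0) over ground-truth rings;
- adapted Rand error with α = 0.5 (the standard choice; the formula
  leaves α free), computed over pixels with non-zero ground truth;
- PQ = SQ × RQ with SQ the mean matched IoU and
  RQ = |TP|/(|TP| + ½|FP| + ½|FN|);
- boundary MAE/MedAE: per-point minimum Euclidean distance from
  predicted boundary points (polyline vertices, or 8-connected mask
  contours when only a mask exists) to the matched instance's
  ground-truth contour pixels, in full-resolution pixels;
- ENCE over U = 100 equal-count bins sorted by predicted σ (stable
  sort; ties keep input order; U reduces to the point count when
  smaller). The default `"variance"` form averages
  |mVAR − RMSE|/mVAR per bin, comparing the mean predicted variance
  directly against the RMSE; the dimensionally consistent form
  |√mVAR − RMSE|/√mVAR is also implemented
  (`ence_variant="standard"`), and reports record which variant was
  used.

## Synthetic data generator

The generator (`synthetic`) produces the statistical structure the
method assumes, not photorealism: concentric rings around a pith with
smooth per-angle width variation (low-order Fourier perturbations, so
the smoothness the bilinearly-upsampled regression head assumes holds
by construction), wedging rings created by clamping the width to zero
where a smooth angular dip crosses it (one contiguous zero arc per
wedge; the innermost ring never wedges so the pith stays enclosed),
dark boundary bands 1–3 px wide, a visually distinct pith that can
optionally be rendered background-like (emulating piths torn off
during thin-sectioning), light background outside the xylem, and
Gaussian texture noise. Defaults: 256-px images, 5 rings of mean
width 18 px (15% relative per-angle variation), 16-px pith, 25%
wedging probability per eligible ring, noise σ = 6 intensity units,
no pith damage (damage is an opt-in stressor).

What passing tests on this generator do and do not show: they
validate the geometry, losses, training scheme and metrics end to
end, and that the networks can learn the task when boundary evidence
is a learnable image feature. They do not show performance on real
thin sections, where boundaries are defined by cell-anatomical
transitions (vessel size gradients, fibre walls) rather than
darkened bands, and where staining, illumination and preparation
artifacts dominate the difficulty.

## Desk-scale study sizes

The reference experiments (`experiments`, also run by
`scripts/acceptance.py`) use sizes chosen for a single CPU: 256-px
images, 40 training / 10 held-out sections of 3–6 rings, a 16-channel
segmentation net trained 50 epochs, a 12-channel regression net
(pyramid width 32) trained 30 epochs with K = 3 unrolling, polar
images with N = 48 rows and M capped at 128 columns, cosine-annealed
Adam from 1e−3 to 1e−5 with 8-step gradient accumulation. Full-scale
defaults (N = 256, no angular cap, 1000/500 epochs) remain the
package defaults in `RunConfig`. Under the desk-scale study the
package reaches, on held-out synthetic sections: mAR ≈ 0.72,
PQ ≈ 0.86 (argmax-on-boundary-map baseline: 0.43/0.62), pooled
boundary MedAE ≈ 1 px; the oracle-in-the-loop geometry test reaches
PQ ≈ 0.96 with MedAE 0; the uncertainty head recovers a known
Laplace noise profile within a few percent (1200 training draws),
with standard-variant ENCE below 0.1.
(These figures are recomputed, not asserted, by
`scripts/acceptance.py`; the test suite asserts the weaker bounds it
states.)

## Numerical choices and conventions

- Pixel coordinates are (row, col), 0-based, pixel centers at integer
  coordinates; angles start at image-east and increase
  counter-clockwise on screen; boundaries are stored as radii at M
  equally spaced angles (star-shaped by construction, which also
  makes angular re-sorting before rasterization unnecessary).
- Downscaled→full mapping is `full = f·ds + (f−1)/2` everywhere.
- Bilinear interpolation with fill value 0 outside the image;
  nearest-neighbour sampling for label lookups.
- The ray-marching step is 0.5 px for boundary extraction and 1 px
  for the ring-width estimate; extracted radii are offset by half a
  step (the true edge lies between the last inside and the first
  outside sample).
- Angular sorting ties (equal angle) cannot occur in the radii
  representation; ENCE bin ties are broken by stable sort order.
- Checkpoints are .npz archives of the parameter arrays plus the
  architecture hyperparameters.

## Known limitations

- The neural-network stack is a compact numpy implementation
  (reverse-mode autodiff, im2col convolutions, Adam); it is
  single-threaded BLAS-bound and intended for desk-scale models, not
  GPU-scale training.
- Only circular (concentric) ring geometry is supported; linear
  increment-core geometry is out of scope.
- The pith detector is the weakest link on damaged piths, and errors
  there propagate through every subsequent iteration — mitigated by
  the `pith_override` hook, not solved.
- σ is reported in downscaled pixels; the overlay writer scales it by
  the downscale factor for display on the full-resolution image.
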