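# ringseg

Iterative ring-boundary instance segmentation for anatomical
cross-section images.

Tree-ring analysis at the cellular level (quantitative wood anatomy)
needs every growth ring delineated as one instance before anything
per-ring can be measured. In microscopic cross sections of arctic
shrubs the rings are concentric, often only a few cells wide, and
they *wedge* — pinch to zero width over an arc and reappear — which
defeats generic instance-segmentation models. `ringseg` segments such
sections ring by ring, walking radially from the pith outward:

1. a **semantic segmentation net** finds the pith, the ring tissue,
   the background and the boundary evidence on a ×4-downscaled image
   (binary dice losses weighted 0.1 / 0.01 / 1.0);
2. from the current ring boundary, a robust **ring-width estimate**
   `P = 1.5 × 95th percentile` of ray-to-boundary distances sizes a
   **polar image**: a 6×N×M resampling (image + semantic logits +
   normalized center distance) whose rows fan radially outward from
   the boundary with step P/N;
3. a **radial regression net** — circular convolutions in the angular
   dimension, instance norms, a dilated context pyramid, a feature
   bypass and an N×1 radial average pooling — predicts for each of
   the M angles the normalized distance δ ∈ [−1, 1] to the next
   boundary, `n(d) = (d − N/2)/(N/2)`, trained with summed L1 loss;
4. the boundary advances by `(δ+1)·P/2` pixels per angle and the
   loop repeats until the ring-width estimate is *absent* (bark or
   xylem edge reached); the boundary polygons are then upscaled and
   rasterized outside-in into a full-resolution instance mask.

Exactly one distance per angle means exactly one boundary per step —
by construction there are no doubled or broken edges. Optionally the
regressor also outputs a per-angle Laplace scale b trained with the
negative log-likelihood `Σ |δ − n(d)|/b + log b`, giving a calibrated
per-angle position uncertainty `σ = √2·b·P/2` in pixels.

Training uses **iterative unrolling**: instead of running K = 3
iterative steps per training step, the steps are spread over K
epochs through disk-backed boundary state, so every batch mixes
images and iteration steps; semantic predictions are computed once
and cached.

The package ships a **synthetic section generator** (concentric
smooth rings, wedging, narrow rings, torn-off piths) so the whole
pipeline is testable without any dataset download, and the full
evaluation suite: mAR, adapted Rand error, PQ/SQ/RQ, boundary
MAE/MedAE and ENCE, all verified against brute-force oracles.

## Worked example

```python
import numpy as np
from ringseg.config import RunConfig
from ringseg.experiments import make_dataset, tiny_config
from ringseg.inference import GroundTruthRegressor, predict
from ringseg.metrics import evaluate_pair
from ringseg.semantic import derive_semantic_targets, SemanticOutput
from ringseg.synthetic import SyntheticSpec, generate_sample

# one synthetic shrub section: 6 rings, some of them wedging
image, mask = generate_sample(
    SyntheticSpec(seed=5, n_rings=6, wedging_prob=0.4, mean_ring_width=15)
)

# drive the iterative loop with the ground-truth oracle regressor to
# inspect the geometry in isolation
targets = derive_semantic_targets(mask, factor=4)
logits = np.stack([np.where(targets[k], 8.0, -8.0)
                   for k in ("pith", "background", "ring", "boundary")])
pred = predict(image, None, GroundTruthRegressor(mask, 4), RunConfig(),
               semantic=SemanticOutput(logits=logits.astype(np.float32)))
report = evaluate_pair(mask.labels, pred.mask.labels)
print(pred.n_rings, round(report.pq, 3), round(report.medae, 1))
```

prints

```
6 0.971 0.0
```

— all 6 rings recovered, panoptic quality 0.971 against the ground
truth, median boundary error 0.0 px: the polar-grid iteration is
near-lossless, so end-to-end quality is governed by what the two
networks learn. Training the tiny reference models
(`ringseg.experiments.run_end_to_end`, 40 synthetic training images,
10 held-out) reaches mAR ≈ 0.72 and PQ ≈ 0.86, against 0.43 / 0.62
for a naive per-column argmax on the boundary probability map.

## Command line

```sh
ringseg synth     --config spec.yaml --out data/ --count 40
ringseg train-seg --config cfg.yaml --data data/ --out seg.npz
ringseg train-reg --config cfg.yaml --data data/ --seg-ckpt seg.npz --out reg.npz
ringseg predict   --image data/image_0000.png --seg-ckpt seg.npz \
                  --reg-ckpt reg.npz --out pred/
ringseg evaluate  --gt data/ --pred pred/ --out report.json
```

`ringseg predict` writes `mask.png` (16-bit label image),
`boundaries.json` (center, per-ring radii, per-point σ) and
`overlay.png` (boundaries with ±1σ envelopes). `--pith pith.json`
supplies a user pith for material on which the detector fails.

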