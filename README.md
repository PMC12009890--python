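# densecount

Density-map counting of clustered fruit from point-annotated RGB field
imagery.

Counting densely clustered fruit (the motivating crop is red clustered
pepper photographed from a low-altitude UAV) with bounding boxes is
impractical: targets are small, heavily occluded and number in the
hundreds per frame. The standard alternative is **density-map regression**:
each fruit is annotated with a single point at its centre, the points are
converted into a non-negative ground-truth density map `M` with
`sum(M) = N` (the count), and a CNN learns to regress `M` from the image.
Counting then reduces to integrating the predicted map.

This package implements that pipeline end to end:

* **Classical ground-truth generators** — fixed-bandwidth Gaussian
  smoothing (FDM) and geometry-adaptive bandwidths from k-nearest-neighbour
  distances (ADM).
* **Learnable density maps (LDM)** — a windowed-attention encoder predicts,
  at every stride-8 grid cell, a `k²` vector encoding a `k x k` kernel
  `K_p`. For each annotation `p_j` the local kernel is normalised,
  `K̃_pj = vec⁻¹(K_pj) / sum(K_pj)`, and stamped at the point:
  `M(p) = Σ_j K̃_pj(p − p_j)`. Because every stamped kernel sums to one,
  `sum(M) = N` holds for *any* generator weights — training reshapes the
  mass around each fruit but cannot corrupt the count.
* **The counting network (MFEN)** — a VGG-16-style 10-layer front end feeds
  three parallel columns of dilated residual modules (kernel sizes 3/5/9,
  hybrid dilation schedules `(1,3,7,1,3)`, `(1,5,13,1,5)`, `(1,9,17,1,9)`),
  each closed by channel+spatial attention (CBAM); columns are fused by
  element-wise summation and a 1x1 head emits the non-negative density map.
  The dilation ladders obey the hybrid-dilated-convolution rule (rates with
  gcd 1), which the `geometry` module verifies by brute-force support
  enumeration: stacked rates `1,2,3` cover their full footprint while a
  single 3x3 dilation-2 layer touches only 9 of 25 pixels.
* **Joint training** — generator and counter are optimised together under
  `loss = Σ_i ||M̂_i − M_i||² + λ Σ_i (1 − CS(M̂_i, M_i))`, where CS is the
  cosine similarity of the flattened maps (with a ζ = 1e-8 guard).
* **Metrics** — MAE, RMSE, SMAPE and R² over per-image counts.
* **Synthetic scenes** — a Neyman–Scott clustered point process plus a
  simple renderer emulate the statistical structure of clustered-fruit
  imagery (count bins 13–68 / 69–124 / 125–180 / 181–235, clustering,
  scale variation, two lighting regimes), so everything is testable
  without field data.

All neural components run on a small, gradient-checked reverse-mode
autodiff engine built on numpy (`densecount.autodiff`, `densecount.nn`), so
the package has no deep-learning-framework dependency.

## Worked example

Generate a tiny synthetic dataset and build ground-truth maps:

```
$ densecount synth --out demo --n-train 8 --n-val 0 --n-test 4 --seed 0 --size 128
dataset written to demo

$ densecount densmap --method fdm --annotations demo/train_00000.json --out fdm.npz --kernel-size 16
density map sum = 60.0000 (n = 60)

$ densecount densmap --method adm --annotations demo/train_00000.json --out adm.npz
density map sum = 60.0000 (n = 60)
```

The printed sums equal the number of annotated points in the file — the
count-conservation guarantee that makes density maps valid counting
targets.

Receptive-field ladders of the three counting columns and the parameter
budget:

```
$ densecount rfield --kernel 3 --dilations 1,3,7,1,3
3 9 23 25 31
$ densecount rfield --kernel 9 --dilations 1,9,17,1,9
9 81 217 225 297
$ densecount params
13140232
```

The kernel-3 column sees 31 stride-8 cells after five layers, the kernel-9
column 297; the full network holds 13.14 M trainable parameters.

Joint training at smoke scale (tiny widths, 30 steps on one CPU — enough to
watch the optimisation work, far too short to produce a useful counter):

```
$ densecount train --data demo --out run --tiny --steps 30 --batch-size 4 --seed 0 --lr 1e-4
final loss 242.1249 after 30 steps

$ densecount predict --weights run/counter.npz --image demo/test_00000.png --out pred.npz --tiny
predicted count = 90.52
```

Every artifact-producing command writes a `run_config.yaml` snapshot next
to its outputs, so runs are reproducible from snapshot + seed.

## Layout

```
src/densecount/
  autodiff.py        reverse-mode autodiff on numpy (gradient-checked)
  nn.py              Module/Parameter, Conv2d, Linear, LayerNorm, checkpoints
  io.py              Labelme-style point annotations, tiling, density-map files
  geometry.py        receptive fields, hybrid-dilation rule, gridding coverage
  dmg_classical.py   FDM / ADM generators, kernel normalisation and stamping
  ldm_generator.py   windowed-attention kernel generator, differentiable stamping
  mfen.py            front end, DRM1/2/3 columns, CBAM, fusion, counting head
  training.py        joint loss, Adam, augmentation, joint training loop
  metrics.py         MAE / RMSE / SMAPE / R²
  synthetic_data.py  clustered-scene generator and dataset writer
  cli.py             synth / densmap / train / eval / predict / rfield / params
```

See `docs/methods.md` for the model assumptions, parameter choices and
limitations.
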