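# Methods

## Problem setting

Given an RGB field image and one point annotation per fruit, the package
estimates the per-image count by regressing a stride-8 density map whose
element sum is the count. Two model families cooperate: a *ground-truth
generator* that turns point annotations into target maps, and a *counter*
that regresses those maps from pixels. The package's central design
guarantee is **count conservation**: every generator — fixed, adaptive or
learned — stamps one kernel per annotation, each normalised to sum to one
and renormalised over in-bounds cells when clipped by a border, so
`|sum(M) − N| ≤ 1e-4` holds unconditionally. For the learnable generator
this means joint training can only redistribute mass around each fruit,
never inflate or deflate the target count.

## Ground-truth generators

**FDM.** One truncated Gaussian for all points. `kernel_size` (grid cells)
sets the window side (nearest odd integer ≥ `kernel_size`) and the
bandwidth is `σ = kernel_size / 4`. The σ-to-window mapping is a choice:
the convention truncates the Gaussian at ±2σ, and it preserves the
qualitative ordering between the small (4) and large (16) settings.

**ADM.** Geometry-adaptive bandwidth `σ_j = β · mean(distance to knn
nearest neighbours)`, measured in image pixels and divided by the stride on
the grid; defaults `knn = 3`, `β = 0.3`, the canonical adaptive-kernel
construction for clustered scenes. Images with `N ≤ knn` fall back to the
fixed rule (kernel size 16). No formula for the adaptive variant is
canonical beyond this construction; both defaults are exposed.

**LDM.** A hierarchical windowed-attention encoder: 4x4 patch embedding to
width `c`, one block group at stride 4, a 2x merge to width `2c`, two more
groups at stride 8, with the second group's output added element-wise to
the third group's output before a linear head to `k²` channels. Element-
wise addition is the only shape-compatible parameter-free reading of
"integrating" the two streams; concatenation would change widths.
Defaults: `c = 96`, window `M = 8`, depths `(2,2,2)`, heads `(3,6,6)`,
`k = 7` (≈56 px of image-space support at stride 8). Only the patch size
(4), the three-group layout and the 1/8 output resolution are fixed by the
reference design; the remaining values are the smallest standard settings
consistent with them, and all are configurable. Attention carries no
relative position bias: on a constant image every token is identical and
the kernel map is exactly spatially constant, a symmetry the tests use.
Shifted-window attention masks pairs from different wrapped regions with
`-inf`, so cross-window attention weights are exactly zero.

Raw generator outputs may be non-positive, where the normalising division
is undefined; kernels are therefore clamped at zero before normalisation,
with a uniform `1/k²` fallback when nothing positive remains.
Annotations map to the stride-8 grid by floor division; ground truth,
kernel map and counter output all live at stride 8.

## The counter

Front end: the first 10 convolutions of the VGG-16 topology (widths
64,64,128,128,256,256,256,512,512,512; 2x max-pool after layers 2, 4, 7),
7,635,264 parameters. The base width is configurable (the plan scales as
`w/8, w/8, w/4, w/4, w/2, w/2, w/2, w, w, w`) so that scaled-down
experiments on one CPU remain faithful in topology; the default `w = 512`
reproduces VGG-16 exactly.

Columns: per column, three DRM1, one DRM2, one DRM3, then CBAM. The 1x1
convolutions of DRM1/DRM2 are *shared* between the dilated path and the
concatenation branches — the reading consistent with counting
"three / two / one" 1x1 convolutions per module. Column width `C = 160`;
the first DRM1 maps the 512-channel front-end output to `C`, later modules
preserve it. With kernels 3/5/9 and the Table-style dilation ladders the
full model has 13,140,232 trainable scalars (13.14 M), within 0.5% of the
13.08 M reference budget; `C` is the knob that sets the back-end size.

Fusion is element-wise summation of the three CBAM outputs (the formal
statement of the reference design; its prose also mentions concatenation —
the equation was followed, keeping the head width at `C`). ReLU follows
every convolution except the attention logits and the final 1x1 head,
which clamps at zero; no batch normalisation. Dilated convolutions use
zero padding `((k−1)·d)/2`, preserving spatial size.

CBAM uses the cited defaults (reduction 16, 7x7 spatial kernel). Note that
channel attention pools *globally*, so exact stride-8 translation
covariance of the whole network holds when the global channel descriptors
of the two inputs agree (the covariance test constructs such inputs); the
convolutional pathway itself is covariant away from borders.

## Joint training

One Adam optimiser over the union of generator and counter parameters,
simultaneous updates (no alternation, no stop-gradient). Per step the GT
maps are rebuilt from the current generator differentiably, the counter
runs forward, and the loss

```
loss = Σ_i ||M̂_i − M_i||² + λ Σ_i (1 − CS(M̂_i, M_i)),   ζ = 1e-8
```

is backpropagated through both models. `λ` defaults to 1.0 — no canonical
value exists for it — and is exposed and logged. Reference optimisation
settings: batch 8, lr 7e-6, L2 regularisation 1e-4, 200 epochs, constant
learning rate. Augmentations: horizontal flip (points mirrored as
`x ← W−1−x`, clamped at the frame edge for sub-pixel coordinates),
brightness scaling `u ~ U(0.8, 1.2)` and Gaussian noise `σ = 5/255`, each
firing independently with probability 0.5.

Initialisation defaults to He/Kaiming. The alternative `gaussian` scheme
(std 0.1 for every layer) is available, but through a 10-convolution stack
it amplifies activations by orders of magnitude and is not a usable
default without pretrained front-end weights, which this package does not
download.

## Evaluation

MAE, RMSE, SMAPE (per-term denominator `(|C_i| + |C_i^GT|)/2`, a 0/0 term
defined as 0) and R² over per-image counts. The estimate is the element
sum of the predicted map; the ground truth is the raw annotation count
(identical to the GT-map integral by conservation, but deliberately
decoupled). R² raises on a degenerate denominator (all GT counts equal).

## Synthetic scenes

The generator emulates the statistical structure of clustered-fruit field
crops: per-image counts drawn from four bins (13–68, 69–124, 125–180,
181–235) with equal bin allocation per split; a Neyman–Scott point process
(parents uniform, offspring counts truncated-Poisson with mean 8, isotropic
Gaussian offsets σ = 18 px) that yields Clark–Evans indices below 1;
red elliptical fruit with radius 4–7 px (small) or 10–16 px (large),
aspect 0.6–1.0 and hue jitter; foliage-coloured occluders over fruit
peripheries (never the annotated centre); and two lighting regimes
(midday, and a darker gradient-lit evening). These defaults were chosen
once to give visually dense 640 px scenes in the stated count range.

It does **not** emulate perspective, 3-D canopy geometry, motion blur or
real foliage texture, so passing tests demonstrate the pipeline's
correctness and trainability on clustered point-annotated imagery — not
field-level accuracy of any trained weights.

## Numerical and scaling choices

* All computation is float64 on a numpy-based reverse-mode autodiff engine;
  every primitive is checked against central finite differences.
* Density-map containers store values in float32 (`.npz` or `.h5`).
* The joint-training smoke configuration uses tiny widths (column width 16,
  front-end base 32, embed dim 24, window 4, kernel k = 5) on 128 px
  scenes with batch 4, 50 steps and lr 1e-4 — a sane rate for an
  un-pretrained tiny model, chosen a priori; the reference 7e-6 assumes an
  ImageNet backbone and a 200-epoch schedule.
* Receptive-field and gridding analyses are exact brute-force support
  computations, not approximations.
* Degenerate stamping cases: a kernel whose whole mass falls out of frame
  degenerates to a delta at the annotated cell.

## Known limitations

* No pretrained front-end weights; all experiments in-repo start from
  random initialisation.
* The gridding analysis covers stride-1 cascades only (the counter's
  columns are stride-1 throughout).
* `hdc_valid` treats the whole rate list as a single group.
* Training at the full reference scale (640 px, default widths, 200
  epochs) is far outside single-CPU reach; the package is exercised at
  smoke scale and the full configuration is validated analytically
  (shapes, parameter budget, receptive fields, conservation).
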