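# Methods

## Model

The method is unpaired image-to-image translation between a low-dose CT
domain X and a normal-dose domain Y. Generator G : X → Y denoises; F : Y → X
re-noises; discriminators D_X and D_Y score 4×4 grids of local patch
probabilities (mean = image score). The training objective combines, per
step: the two adversarial terms, λ times the L1 cycle-consistency of both
reconstruction directions, and a perceptual L1 distance between frozen deep
features of each image and its cycle reconstruction. λ defaults to 10.

### Generator

Three branches produce H×W×C feature maps from the single-channel input:

* **Residual encoder–decoder branch** — `redcnn_layers` 3×3 convolutions
  followed by the same number of 3×3 "deconvolutions", all stride 1, ReLU
  after every layer. Shortcut connections add the encoder feature of stage k
  to the pre-activation of the symmetric decoder stage for every other pair;
  the exact placement is an open design point, and every-other-pair was
  chosen as the lightest scheme that preserves the convergence benefit.
* **U-Net branch** — `unet_layers` stride-2 4×4 convolutions down, the same
  number of stride-2 transposed convolutions up, skips by concatenation, and
  a final 3×3 fusion convolution that also sees the raw input. The strided
  depth auto-reduces (with a warning) when the input is too small, so the
  same module runs at 256 and at test sizes.
* **Pointwise branch** — one 1×1 convolution, no activation: purely
  cross-channel, no spatial mixing.

Selective-kernel fusion computes the channel descriptor S by global average
pooling of U₁+U₂+U₃, a compact feature Z = ReLU(Norm(W_s S)) with
d = `reduction_dim` (default max(C/2, 8)), three per-branch d→C linear heads,
and a per-channel softmax over the three logits; the fused map is the
convex combination of the branch maps. The weighted operands are the raw
branch outputs (the literal per-channel form), not post-sum residuals. A
final 1×1 convolution maps to one output channel with no activation; an
optional residual (input + output) mode exists but is off by default.

**Normalization choice.** The compact-feature normalization is specified as
a batch-style normalization, but the training regime is batch size 1, where
batch statistics over a vector are degenerate (zero variance per feature).
The implementation therefore standardizes Z's pre-activation across its own
feature dimension with learnable gain and bias (layer-norm style), which is
well defined at any batch size and keeps the logits in a stable range.

### Discriminator

A PatchGAN ladder of 4×4 stride-2 convolutions with LeakyReLU(0.2) between
layers and a sigmoid output: 6 stages for 256×256 inputs
(64→128→256→512→512→1 channels, capped at 512), 4 stages for 64×64 test
inputs — in both cases ending at the 4×4 grid. Each grid entry sees a strict
sub-region of the input (verified by perturbation).

### Perceptual extractor

A VGG-16-topology stack (13 3×3 convolutions in five blocks with 2×2 max
pooling) whose features are taken after the second pooling stage (128
channels at full width) and the last pooling stage (512 channels). The
extractor is frozen. Its default weights are a fixed-seed random
initialization with He scaling (sd √(2/fan-in)); the scaling matters —
with small-variance weights the activations decay exponentially across 13
layers and the distance becomes uninformative. Random fixed features are a
standard choice for perceptual distances when no pretrained network should
be a dependency; true VGG-16 weights can be loaded from a local file via
`weights_source="pretrained_vgg16"`. `vgg_width_factor` scales all widths
(tiny profile: 1/8).

### Optimization

Adam (β₁ = 0.9, β₂ = 0.999 — conventional defaults, not separately
specified) at batch size 1; discriminators update first on detached fakes,
then both generators jointly. The learning rate is flat at `lr_init`,
linearly decayed between `decay_start_step` and `decay_end_step` to
`lr_final`, flat thereafter. Full-scale values: 1e-5 → 1e-7 over steps
100 000–700 000 of 1 000 000. The literal log adversarial form is the
default; the least-squares form is provided (and used by the tiny profile)
because log-loss cycle GANs are notoriously unstable at small scale. No
image-history pool is used by default. The batch schedule is a pure function
of (seed, step) — each domain follows its own per-epoch permutations — which
is what makes checkpoint resume bit-exact.

## Synthetic data

The phantom generator emulates the clinical setting: 512×512 slices in
[0, 1], soft tissue in the 0.2–0.3 band (so the 0.2–0.28 display window is
meaningful), optional ~0.03 lung cavities (for the 0–0.33 window), drawn as
random ellipse composites inside a body outline. Low dose is simulated in
the sinogram domain: parallel-beam Radon transform of the attenuation map
(`mu_per_pixel` = 0.05 per unit intensity), Poisson counts at `photons_i0`,
additive Gaussian electronic noise (sd 0.5 counts), log conversion, ramp-
filtered back-projection, clipping to [0, 1]. This produces the correlated,
streaky noise signature of low tube current; variance decreases monotonically
in `photons_i0` (verified by Monte-Carlo). A fast image-domain Gaussian mode
exists for cheap tests. What the simulator does **not** model: beam
hardening, scatter, helical/fan-beam geometry, detector cross-talk, anatomy
beyond piecewise-constant ellipses. Passing tests therefore demonstrate the
method's mechanics and trainability on physically plausible noise, not
clinical performance.

Patches are extracted on a regular grid (every `stride` pixels, row-major;
256/16 at full scale, giving 289 per 512×512 slice). Domains X and Y come
from disjoint subject cohorts and are shuffled independently; clean
counterparts of X patches exist only in a held-out evaluation split that the
training iterator cannot reach (enforced by test).

## Tiny profile (CPU-scale study conditions)

All sizes scale down together: 96×96 slices, 64×64 patches at stride 32,
2+2 subjects × 2 slices (16 patches per domain), 20 held-out evaluation
patches, C = 16 channels, branch depths 3, d = 8, 4-stage discriminator,
1/8-width perceptual extractor, least-squares adversarial form, Adam lr
2e-4 decayed to 2e-5 over the last 400 of 1000 steps, `photons_i0` = 2000
vs clean references. These values were chosen once as a realistic
miniature of the full-scale regime that trains on a single core in a few
minutes; the full-scale profile (`full`) keeps the original values.

## Metrics

RMSE and PSNR follow their standard per-image definitions (MAX = 1 on the
normalized scale; identical images return an infinite-PSNR sentinel with a
warning). SSIM uses the two-factor form with k₁ = 0.01 and k₂ = 0.02 (note:
k₂ = 0.02 rather than the more common 0.03 is deliberate and kept as the
default; the c₃ = c₂/2 constant belongs to the three-factor form and is
unused). Local statistics use an 11×11 Gaussian window (σ = 1.5, truncated,
sample-covariance normalization, half-window border crop) — the field
convention; the bare global-statistics form is available with
`window=None` and is used for the closed-form worked example. Display
windowing (0.2–0.28 tissue, 0–0.33 lung) is a linear rescale with clipping
used only for rendering, never inside losses or metrics.

## Numerical choices and edge cases

* Everything is float32; metrics accumulate in float64.
* Parameter init: truncated normal (sd 0.02, clipped at 2σ), zero biases,
  seeds fixed per network (the perceptual extractor uses He scaling, above).
* Log arguments are floored at 1e-8; sinogram counts at 1 before the log.
* Patch extraction requires patch ≤ image and stride ≥ 1; degenerate SK
  configurations (d ≥ C) warn rather than fail.
* Non-finite losses abort the step with a tensor dump for diagnosis.
* Inference on images larger than the training patch tiles with half-tile
  overlap and uniform-average blending.

## Known limitations

* The NumPy engine is single-device and unbatched in spirit; the full-scale
  profile's million-step run is far outside its intended envelope.
* Random-feature perceptual distances are weaker texture priors than
  pretrained features.
* The tiny study shows a reliable PSNR gain over the noisy input but its
  absolute numbers say nothing about clinical data; the unpaired clinical
  regime the method targets cannot be scored quantitatively at all without
  paired references.
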