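# Methods

## Problem and model

The package addresses dataset enlargement for computer-aided diagnosis:
labeled CT slices with tumors are scarce, so we synthesize new ones by
*inpainting*. A lesion-shaped region of a slice is whitened to the value
4096 (one above the 12-bit maximum of 4095; stored literally, clamped only
when exporting to integer containers), producing the *attention map*. A
conditional GAN learns to replace the white region with plausible lesion
gray values and texture while reproducing the rest of the slice.

**Generator.** Two weight-independent contracting paths encode the whitened
image and the attention map. Each block is pre-activation ReLU → stride-2
convolution → batch norm (the first block drops the leading ReLU on raw
input; the final block drops BN — see *Numerical choices*). The leading
blocks use dilation-2 convolutions (kernel 4, padding 3, effective kernel 7,
still exactly halving the side) so early layers integrate context beyond a
small neighborhood; once maps are smaller than 32×32 regular kernel-4/
stride-2/padding-1 convolutions take over. At the canonical 512×512 input
the per-block sides are 256 … 1 with channel schedule
64, 128, 256, 512, then 1024 capped — a 1×1 bottleneck with 1024 feature
maps. The two bottlenecks are concatenated and merged by a 1×1 convolution.
The decoder uses transposed convolutions (kernel 4, stride 2, padding 1 —
chosen knowing they produce the classic early-training checkerboard
artifact), BN and ReLU; the final block is a bare transposed convolution
with **linear** output. Dropout (rate 0.5) acts in the three coarsest
decoder blocks during training only.

**Residual connections.** Decoder activations at side `2^j` receive encoder
features from the matching scale additively. At scales with at most 1024
flattened positions (side ≤ 32) the connection is a trainable dot-product
attention: 1×1 projections A (image path), B (attention-map path) and V
(image path); `S = AᵀB` over flattened positions; `D` = column-wise softmax
of `S` (each column of D is a distribution over source positions); output
`j` = Σᵢ D[i,j]·Vᵢ. At finer scales an N×N similarity matrix is infeasible
(N = 262 144 at side 512) and the connection degrades to a plain additive
skip of both encoder streams. Attended output *adds* to the decoder stream
(replacing nothing), matching the residual-connection reading.

**Discriminator.** Six blocks over the channel-concatenated
(image, attention map) pairing: four kernel-4/stride-2/padding-1 blocks
(channels 64–512), two kernel-4/stride-1/padding-1 blocks (512, then 1).
This is the unique standard patch-discriminator geometry that reproduces,
from a 512 input, a 30×30 probability map = 900 patches with a 142-pixel
receptive field (recursion `rf += (k−1)·jump; jump *= s`). BN is omitted
from the first and last blocks; the last block ends in a sigmoid. The
scalar verdict is the arithmetic mean of the map.

**Objective.** The discriminator maximizes
`mean log D(A) + mean log(1 − D(B))` (probabilities clipped to
[1e−7, 1−1e−7]); the trainer minimizes its negation. The generator
minimizes `λ₁·L1 + λ₂·(−mean log D(B))` with λ₁ = 100, λ₂ = 1 — the
non-saturating adversarial term the 100:1 weighting implies. A strict mode
(`strict_l1_generator`) trains the generator on L1 alone. At training time
both encoder inputs are the whitened slice (the inference-time situation);
`strict_original_input` feeds the intact original to the image path instead.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| learning rate | 2·10⁻⁴ | Adam step size, both networks |
| Adam β₁ / β₂ | 0.5 / 0.999 | momentum coefficients (β₂ unstated upstream; Adam default) |
| λ₁ / λ₂ | 100 / 1 | weights of L1 and adversarial terms |
| exponential decay | 0.99 | learning-rate factor applied once per epoch |
| batch size | 1 | per-sample batch norm statistics |
| epochs | 10 | passes over the dataset |
| dropout | 0.5 | three coarsest decoder blocks, training only |
| loss log / checkpoint every | 100 / 500 | iterations |
| white value | 4096 | whitening intensity of masked pixels |
| PSNR data range | 4095 | 12-bit convention; configurable |

Normalization follows `(value − mean) / std` with per-slice statistics and
the population (divide-by-n) standard deviation; the statistics are stored
so the transform inverts to 1e−4. The attention map is standardized with
its source slice's statistics so the white value stays maximal. A
configurable flag for global (dataset-level) statistics exists on
`normalize_slice`'s caller side by passing precomputed statistics — per-slice
is the default because the formula is applied per image.

## Phantom generator: what it emulates, what it does not

Phantoms emulate the *structure* the networks must exploit: a 12-bit
intensity range, an elliptical organ with band-limited (Gaussian-smoothed
white noise) texture inside a stated intensity band (default 1000–1300,
liver-parenchyma-like on a +1024-offset scale), an air/soft-tissue
background, and 1–3 compact rotated-elliptical lesions strictly inside the
organ, hypodense (offset below the band) with higher-frequency texture.
Defaults describe a 512×512 slice; `PhantomSpec.scaled(64)` shrinks the
geometry proportionally for CPU runs. Generation is deterministic per seed;
dataset items use counter-based child seeds (`SeedSequence(master,
spawn_key=(i,))`) so item i is independent of generation order.

Phantoms are *not* anatomically realistic: no ribs, vessels, partial-volume
effects, scanner noise spectra, or inter-patient variability. A green
desk-scale test therefore establishes that the architecture, losses,
optimization and seeding behave as specified and that the generator can
learn a texture-contrast inpainting task — not that it reaches any
clinical-quality bar on real CT.

## Numerical choices

- **float32** activations/parameters; similarity softmax is max-stabilized.
- **BN at evaluation** uses the current input's statistics (deterministic;
  the pix2pix test-time convention). Running averages are tracked but
  disabled by default: with batch 1 the 1×1-bottleneck batch variance is
  identically zero, the running variance collapses, and dividing by
  √eps amplified parameter drift ~300× in eval mode.
- **No BN in the final encoder block**: at 1×1 spatial size with batch 1,
  BN outputs the constant shift β regardless of input, zeroing all gradient
  to the bottleneck convolution (caught by the gradient-flow property
  test). The innermost block is conv-only.
- **Probability clipping** at 1e−7 before logs prevents −inf on saturated
  sigmoids; gradients pass only inside the clip interval.
- **Masks under augmentation** resample nearest-neighbor and re-binarize at
  0.5; exact multiples of 90° rotate by grid permutation (no interpolation).
  A transform that would annihilate a mask keeps its center pixel.
- **PSNR** returns +inf for identical images; dataset means exclude
  infinities and report their count.
- **Degenerate inputs**: constant slices cannot be standardized
  (`DegenerateImage`); empty masks cannot be harvested (`EmptyMask`);
  out-of-image stencils raise `OutOfBounds`.

## Open design points resolved

- Softmax axis: the denominator sums over `i`, so D is column-stochastic;
  `j` is read as a flattened spatial position.
- The value projection V is not defined upstream; we use a third learned
  1×1 projection of the image-path features (standard attention form).
- "Exponential decay 0.99" is applied to the learning rate once per epoch.
- Update order: one discriminator step, then one generator step, per
  iteration; the generator's adversarial term is evaluated against the
  just-updated discriminator.
- Augmentation draws (source patch, transform) pairs with replacement after
  returning the originals; rotations are continuous in [0°, 360°), scales
  uniform in [0.75, 1.25].
- Whether raw LiTS-style intensities were clipped to [0, 4096] before
  normalization is unknowable here; the phantom generator simply emits that
  range.

## Known limitations

- Batch size is fixed at 1 (per-sample BN; the attention fusion assumes it).
- The numpy engine is CPU-bound: canonical 512×512 forward passes take tens
  of seconds, so canonical-scale *training* is out of reach — desk-scale
  (64×64) training is the supported regime, and the published LiTS-scale
  PSNR/Dice numbers are not reproducible by this artifact.
- No DICOM input, no 3D synthesis, no SSIM/FID metrics.
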