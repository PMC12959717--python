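# Methods

## Model

The network is a U-shaped encoder–decoder for binary (vessel/background)
semantic segmentation of 8-bit RGB histology tiles whose sides are
divisible by 32. Inputs are scaled per channel to [0, 1]; no other
normalization or augmentation is applied.

**Encoder.** A 3×3 stride-2 convolution (BN, ReLU, width 64) forms the
stem; four stages of residual basic blocks follow at output strides 2, 4,
8 and 16 with widths 64/128/256/512 and 2/3/2/2 blocks per stage (the
first block of stages 2–4 downsamples with a projection shortcut). Every
block gates its two-convolution main branch with depthwise-separable
channel attention before the residual addition: adaptive average pooling
to C×2×2 — rather than global pooling, so a little spatial structure
survives the squeeze — then a depthwise 2×2 convolution to C×1×1, a
pointwise 1×1 convolution to restore cross-channel correlation, BN and a
sigmoid. Keeping the gate off the identity path preserves gradient flow
through the shortcut. Convolutions carry no biases (BN supplies the
affine terms); BN uses eps 1e-5, momentum 0.1.

**High-semantic layer.** When enabled, one further residual block
downsamples to stride 32 at width 896, and a global-context head — global
average pooling, 1×1 reduction to 344 channels, ReLU, 1×1 expansion —
broadcast-adds a learned context vector back onto the map, giving the
deepest features an image-wide receptive field. When disabled, a
parameter-free 2×2 max-pool of the stride-16 map stands in as the
stride-32 pyramid entry.

**Skip attention.** Each skip-bound map (strides 2–16, plus the stride-32
map in the full configuration) is gated by parallel channel + spatial
attention: the channel branch reuses the channel-attention pipeline up to
its pre-sigmoid logits; the spatial branch is a depthwise 3×3, a pointwise
convolution to one channel, and BN. The two logit maps are broadcast and
summed point-to-point, and one sigmoid maps the sum into (0, 1) — summing
after the sigmoids instead would allow multipliers up to 2, and channel
concatenation would need an extra convolution to restore the width.

**Decoder.** From the deepest map: bilinear 2× upsampling
(corner-excluding alignment), a 1×1 projection to the skip width (BN,
ReLU), elementwise addition with the attended skip, and a 3×3 refinement
convolution. The refinement widths (69, 262, 198, 69 at strides
16/8/4/2), together with the high-semantic width 896 and the context
width 344, are calibrated so that the profiled budgets of the full
configuration (28.37M parameters, 65.23G MACs at 512×512) and of the
plain encoder–decoder variant (13.28M, 61.79G) come out exactly; they are
part of the model definition, not free knobs. After the last skip level a
final 2× upsample, a full-resolution 3×3 refinement (width 64) and a 1×1
head produce two-class logits. There are no transposed convolutions.

**Auxiliary branch (training only).** The five pyramid maps and the final
decoder feature map are bilinearly resized to input resolution,
concatenated (channel width 64+128+256+512+896+64 in the reference
configuration) and compressed to class logits by one 1×1 convolution. Its
cross-entropy against the mask joins the main loss with weight λ = 0.4 (a
conventional deep-supervision weight; the branch's purpose is to inject
multi-receptive-field supervision, and results are not sensitive to λ in
the 0.2–0.6 range at desk scale). The branch never runs at inference, so
it adds zero parameters and zero MACs to every inference profile.

## Profiling convention

The profiler replays one inference-mode forward pass in a shapes-only
trace and tallies the recorded ops, so counts always describe the graph
that actually executes. Convolutions and transposed convolutions count
`C_out·H_out·W_out·(C_in/groups)·kh·kw` multiply-accumulates plus one per
output element when a bias is present; BN counts 2 ops/element, ReLU 1
op/element; pooling, bilinear resizing, elementwise add/multiply and
sigmoid are excluded. This is the convention under which the classic
4-level U-Net baseline (widths 64–1024, two biased 3×3 convs + BN + ReLU
per level, 2×2 transposed-conv upsampling, single-channel sigmoid head)
profiles to 31.04M parameters and 218.98G MACs at 512×512; that baseline
anchors every cross-architecture comparison the package reports.
Parameters count every trainable entry reached in inference, including BN
affine pairs, each exactly once.

## Training

Loss: pixelwise cross-entropy (plus the λ-weighted auxiliary term).
Optimizer: Adam, learning rate 1e-3, batch size 4, optional step decay
(×0.3 every N epochs). All defaults are package choices, exposed in
`TrainConfig`; the underlying task publishes no recipe. Training is
deterministic given the config seed: it drives weight initialization and
data order, and the engine is single-threaded numpy. Parameters are cast
to float32 for training; float64 is used everywhere else (gradient checks
pass at 1e-6 finite-difference tolerance).

## Synthetic data

The generator emulates 512×512 PAS-stained kidney tiles: a background of
smoothed correlated Gaussian noise tinted to a pink–purple palette, over
which 4–10 vessels are drawn — random-walk tubes 2–12 px wide and, for a
configurable fraction (default 0.3), ring-shaped vessel walls with bright
lumina. The mask is the exact foreground support, and the support is
stained uniformly at the configured contrast (default 0.45) with a soft
halo only outside it, so the labels are recoverable from the image — an
invariant the training tests depend on. Everything is drawn from one
`numpy.random.default_rng(seed)` in a fixed order (background field,
vessel count, per-vessel geometry), making pairs bit-identical across
runs and platforms. Datasets are written as PNG (RGB images; masks stored
{0, 255} and binarized at >0 on read) split train/val/test 6:2:2, where
val and test round to nearest and train takes the remainder
(1633 → 979/327/327).

What the synthetic benchmark does not capture: stain variability,
out-of-focus regions, tissue-fold artefacts, true vessel morphology and
annotation noise. Passing the desk-scale tests demonstrates that the
architecture, losses, metrics and compression machinery behave correctly,
not that the model reaches any particular accuracy on real tissue.

## Desk-scale study sizes

CPU budgets dictate reduced problem sizes, chosen once: the training
fixture uses the full architecture (every component enabled) at widths
16/32/48/64, high-semantic width 96, decoder widths 32/48/48/32, on eight
128×128 tiles with vessel widths 3–8 px, trained up to 150 epochs (batch
4, decay ×0.3 every 50). Under seed 0 this overfits to IoU ≈ 0.92; the
residual errors sit almost entirely on the one-pixel mask boundary, where
the rendered stain edge is genuinely ambiguous. Unit tests use a still
smaller 8/16/24/32 configuration at 64×64.

## Compression

**Pruning** removes whole output channels (dense rebuild, not masking)
from structurally free convolutions only: the first 3×3 convolution of
each residual block (consumed only by the block's own BN and second
convolution) and the decoder refinement convolutions (consumed only by
the next projection). Channels coupled across residual additions or skip
fusions are never touched, so no cross-layer index bookkeeping can
desynchronize. Layers are selected deepest-first — the layers farthest
from the input perturb the output least — and within a layer channels are
ranked by the L2 norm of their filter slice, ties breaking toward the
lower index; `ceil(keep_ratio·C)` survive.

**Fusion and INT8 quantization.** Conv-BN pairs fold into single biased
convolutions (`W' = W·γ/√(σ²+ε)`, `b' = (b−μ)·γ/√(σ²+ε) + β`); fusion
equivalence holds to 1e-4 on the assembled network. Post-training static
quantization then stores each compute-bearing convolution's weights as
symmetric INT8 with one scale per output channel (`scale_c = max|w_c|/127`
— per-tensor weight scales measurably exceed the 0.02 IoU budget on the
desk fixture, per-channel is the standard conv deployment choice) and
quantizes each convolution's input per-tensor affine (zero point in
[−128, 127]) using min/max ranges recorded on a calibration set of
training tiles. Convolutions inside attention gates and the context head
stay in float by default: they are control logic carrying a negligible
share of the MACs. A quantized convolution
quantizes its input, accumulates in integer arithmetic and dequantizes
its output; the ops between convolutions (attention gates, resizing,
additions, softmax) stay in float, which is the faithful desk-scale
reading of quant/dequant stubs around the integer layers when the graph
is not a pure conv chain. Degenerate constant activations receive a
guarded minimum scale. Quantized conv weights occupy ~¼ of their float32
bytes; on the trained desk-scale fixture the IoU change from quantization
is within 0.02.

## Numerical and design notes

- Bilinear resizing uses the half-pixel (corner-excluding) convention and
  is implemented as two separable interpolation matrices, which makes its
  adjoint (the gradient) exact.
- Adaptive pooling uses floor/ceil window edges, exact for any output
  size.
- Cross-entropy subtracts the per-pixel max logit (treated as a constant)
  before exponentiation.
- The empty-mask conventions (IoU and P/R equal 1 when both masks are
  empty; a zero denominator with a non-empty counterpart scores 0) keep
  dataset averages defined on degenerate tiles.
- Per-image averaging (with dataset F1 derived from aggregated P and R)
  is the reporting convention; a pooled micro-average over all pixels is
  provided separately and equals the metrics of a mosaic of the inputs.
- Training-only state (auxiliary head) is excluded from profiles by
  construction, because the profiler traces the inference graph rather
  than enumerating module parameters.

## Known limitations

The numpy engine is single-threaded and roughly two orders of magnitude
slower than GPU frameworks, so realistic-scale training is out of scope.
Quantized inference simulates integer kernels with int64 accumulation in
numpy; it reproduces INT8 arithmetic exactly but is not faster than the
float path. The U-Net baseline implements forward inference only (it
exists for profiling and reference computations). Checkpoints are plain
`.npz` archives and make no compatibility promises across package
versions.
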