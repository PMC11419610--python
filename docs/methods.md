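# Methods

This note records the models and procedures implemented in `flexdetect`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data-based tests do and do not establish.

## Problem setting

Soft-bodied marine organisms (holothurians, starfish, jellyfish, octopus)
are hard targets for standard detectors for two compounding reasons: the
water column degrades imagery (low contrast, blue-green color cast, blur,
detail loss), and the animals themselves deform, so a rigid sampling grid
and rigid box-regression penalties fit them poorly. The package implements
the bespoke computational pieces of a detection pipeline adapted to this
setting — an image enhancer, a deformable convolution operator, a
parameter-free attention layer, robust box-regression losses, feature-fusion
blocks, and a detection evaluator — each testable in isolation against
analytic or brute-force oracles, plus a synthetic scene generator that makes
the whole chain measurable without any external dataset.

## Contrast-limited adaptive histogram equalization (enhancement)

For a tile of `M × M` pixels with histogram `H(i)` and CDF `C(i)`, the local
gray-level mapping is `m(i) = 255 · C(i) / M²` (round-half-up). The slope of
`m` is proportional to the histogram height, so bounding the slope by
`S_max` is equivalent to clipping the histogram at `H_max = S_max · M² / 255`.
Clipping is single-pass: with `excess = Σ max(0, H(i) − T)` and
`L = excess / 256`, bins below the threshold `T` become `H(i) + L` and
clipped bins become `T + L`. Total mass is conserved exactly; clipped bins
end slightly above `T`, which is accepted as part of the single-pass
formulation. The image is processed as an `tiles_x × tiles_y` grid (default
8 × 8) of independent tiles whose mappings are blended bilinearly per pixel
by distance to the four surrounding tile centers; edge and corner regions
degrade to linear and constant blending. `M²` is taken as the per-tile pixel
count, so non-square and non-divisible tiles are handled uniformly.

With a single tile and no clipping the procedure reduces to global histogram
equalization — the tests assert agreement within ±1 gray level at every
pixel, and the acceptance script measures the realized maximum difference.

Color is handled on the luma channel of a BT.601 YCbCr decomposition and
recombined, which raises contrast without the hue shifts that per-channel
equalization can produce; a `per_channel` mode exists for comparison.
`S_max` defaults to 4.0 and is exposed as configuration; no specific value
is canonical for underwater footage, and the default sits in the
conventional 2–6 range for clip-limited equalization.

### Boundary enhancement channel

The boundary channel isolates genuine foreground/background boundaries from
texture. A full-resolution Sobel gradient magnitude `B_fine` (after a
1-pixel Gaussian pre-smooth) captures detail; the gradient of a 4× block-
averaged copy, upsampled back, indicates where large-scale structure exists.
The published description constrains only the intent (combine high-level
and low-level features to isolate boundaries); the concrete form used here
is the gated product

    B = normalize( B_fine ⊙ 1[B_coarse > τ] ),   τ = 0.2,

so fine structure without coarse support (noise, high-frequency texture) is
suppressed — the tests construct a period-2 checkerboard, which vanishes
under 4× averaging, to verify exactly this. Fusion is additive:
`out = clip(CLAHE(img) + γ·255·B)`, γ = 0.3 by default. Additive fusion was
chosen over multiplicative or learned fusion because it is the simplest form
that strictly adds boundary energy without re-weighting interior content;
the weight is configuration, and γ = 0 recovers plain CLAHE bit-exactly.

## Deformable convolution

A regular k×k convolution samples on the fixed grid
`R = {(−1,−1), …, (1,1)}`: `y(p₀) = Σₙ w(pₙ)·x(p₀+pₙ)`. The deformable
variant adds a learned fractional displacement per output position and tap:
`y(p₀) = Σₙ w(pₙ)·x(p₀+pₙ+δ_{p₀,n})`, with bilinear interpolation at
non-integer positions and zero padding outside the map. Offsets are
predicted by an ordinary convolution on the layer input and are
zero-initialized, so training starts at the regular-convolution limit.
Offset channels are interleaved `(dy₁, dx₁, …, dy_N, dx_N)` — a fixed
layout is required for reproducible serialization. Only the unmodulated
("v1") semantics are implemented; there is no per-tap modulation mask.

Two independent routes exist and are cross-checked: a plain-numpy reference
(`deformable_conv2d`) and a differentiable layer built on the autodiff
`grid_sample` primitive. Exact properties asserted: zero offsets reproduce
standard convolution; constant integer offsets reproduce a shifted-input
convolution in the interior; the operator is linear in the input for frozen
offsets; analytic gradients for input, weights and offsets agree with
central finite differences to 1e-4 (offsets are kept away from integer
values in gradient checks, where bilinear interpolation has kinks).

The residual unit (`DCNBlock`) is a CBL stem (convolution → batch
normalization → SiLU) followed by two offset-predicting deformable layers
whose composition is summed with a skip connection from the stem output —
the skip is what keeps offset learning stable at initialization. With the
offset predictors zeroed the block is exactly a plain residual convolution
block, asserted in tests.

## Autodiff engine

No deep-learning framework is part of the dependency set, so the package
carries a small tape-based reverse-mode autodiff over numpy arrays
(`flexdetect.autograd`): broadcasting-aware elementwise ops, reductions,
shaping, batched matmul, an im2col convolution primitive, and a bilinear
`grid_sample` primitive differentiable in both the map and the coordinates.
`detach` cuts the tape and implements every "starred" (gradient-stopped)
quantity in the losses. Float64 is used throughout: the blocks run at
smoke-test scale, where verifiability matters more than speed. All
primitives are finite-difference-tested.

## SimAM attention

Each element `t` of a channel is scored by the energy

    E(t) = 4(σ² + λ)² / ((t − μ)² + 2σ² + 2λ),

with `μ` and the biased (1/M) variance `σ²` computed over all M = H·W
elements of the channel, λ = 1e-4. Distinctive elements (large |t − μ|)
have low energy; the attention weight is `sigmoid(1/E)` applied
elementwise. The module has exactly zero learnable parameters. The
statistics include the target element itself, matching the printed
formulation used here; an `exclude_self` flag provides the leave-one-out
variant found in other formulations, default off. Closed-form checks: a
constant channel has `E = 2λ` everywhere and passes through essentially
unchanged (`sigmoid(5000) ≈ 1`); the minimum-energy element of a channel is
always its maximum-deviation element.

## Wise-IoU losses

With boxes in center form and `L_IoU = 1 − IoU`:

    R_WIoU   = exp( ((x−x_gt)² + (y−y_gt)²) / (w_c² + h_c²)* )
    L_WIoUv1 = R_WIoU · L_IoU
    β        = L*_IoU / L̄_IoU
    r        = β · α^(δ−β)
    L_WIoUv3 = r · L_WIoUv1

`w_c, h_c` are the smallest enclosing box sides; the star marks quantities
excluded from gradient flow (implemented with `detach`). The outlier degree
β compares the detached instantaneous IoU loss to a momentum running mean
`L̄_IoU` (update rate m = 0.01); the gain r vanishes at β = 0, equals δ at
β = δ, and decays for large β, so both trivially easy and likely-mislabeled
samples receive small gradient gain. As printed, the β ratio uses the
instantaneous loss in both numerator and denominator and is identically 1;
the running-mean denominator is the only reading under which the mechanism
is "dynamic", and it is the default here. A `literal_eq16` switch implements
the printed form for comparison. α = 1.9, δ = 3 follow the conventions of
the published Wise-IoU method; neither is restated in the source being
followed, and both are exposed as configuration.

CIoU (`1 − IoU + ρ²/c² + αv`, with the aspect term weight treated as a
constant) is implemented as the comparison baseline.

### Robustness experiment

The claim behind WIoUv3 is robustness to low-quality box annotations. The
isolated experiment: 48 target boxes on a 64-unit canvas; a shared 4–16–4
tanh network refines moderately perturbed anchor boxes; supervision uses
labels of which a seeded 10% are heavily jittered (center shifts and size
scalings with σ = 0.8); 400 Adam steps at lr 0.02; the score is the median
`1 − IoU` against the *clean* targets over the clean-label anchors. A shared
predictor is essential: with independent per-anchor parameters the loss
choice would merely rescale per-sample step sizes and corruption could not
propagate between samples. Experiment dimensions were fixed from the design
(moderate size, enough steps for partial convergence) rather than swept.
WIoUv3 is compared with CIoU at equal steps over 5 seeds; the dynamic gain
suppresses the corrupted samples' gradients once their β rises above δ.

## Fusion blocks

**BiC** fuses three adjacent pyramid depths into the middle resolution:
1×1 reduction of the same-depth map, 1×1 reduction then 3×3 stride-2
downsampling of the shallower map, 2×2 stride-2 transposed-convolution
upsampling of the deeper map, concatenation, and a final 1×1 reduction.
Internal branch width defaults to half the output channels (the reduction
targets are not pinned by the source design; half-width is the usual CSP
convention and is configurable). The transposed convolution is implemented
as a 1×1 projection to 4× channels followed by depth-to-space, which is
algebraically identical.

**SlimCSPSPPF** splits its input into a pyramid path — compound 1×1→3×3
convolution, then three cascaded 5×5 stride-1 max poolings with all stages
concatenated — and a 1×1 skip path, then concatenates and reduces. The
kernel sizes of the "compound convolution" are read as 1×1→3×3.

Both blocks accept `norm=False, activation="identity"` harness switches
that remove every nonlinearity except pooling. In that mode BiC is exactly
linear (superposition-tested); SlimCSPSPPF contains max pooling, which is
positively homogeneous but not additive, so the tests assert full linearity
for BiC and positive homogeneity `f(a·x) = a·f(x), a > 0` for SlimCSPSPPF —
exact linearity of a max-pool block is not attainable and is not claimed.
Parameter counts of both blocks are regression-tested against closed forms.

## Detection metrics

Greedy confidence-ordered matching: predictions sorted by descending
confidence (stable, index tie-break), each assigned to the unmatched
same-class ground truth with the highest IoU ≥ 0.5 (lowest GT index on
ties). Precision `TP/(TP+FP)` and recall `TP/(TP+FN)`, with 0/0 defined as
0 for precision and 1 for recall (logged). AP is the exact area under the
right-monotone precision envelope over recall ("all-point" interpolation) —
for step curves this is the exact value of ∫P(R)dR, which is why it is
preferred over 11-point sampling. mAP50 averages the per-class AP over
classes present in the ground truth; absent classes are excluded and
reported. The implementation is verified to 1e-9 against a brute-force
threshold-sweep oracle on 200 random scenes.

Scalar P/R are quoted at the pooled max-F1 confidence threshold, since any
single operating point is otherwise arbitrary; the full curves are part of
the report. The confusion matrix follows the detector-ecosystem convention:
matching at IoU 0.45 with predictions below confidence 0.25 dropped,
cross-class matches allowed (so misclassifications land off-diagonal),
unmatched ground truths in the background row and unmatched predictions in
the background column.

## Synthetic scenes

The generator emulates the documented difficulties of the target imagery:
1–4 organisms per frame from 4 classes, rendered as Fourier-perturbed
ellipses `r(θ) = r₀(1 + Σₖ aₖ cos(kθ + φₖ))` (harmonics 2–4, total
amplitude 0.25 by default) over a smooth teal background; class identity is
a fixed palette/shape signature (elongated dull-brown body; orange
five-lobed outline; pale translucent bell; purple spotted blob) so small
classifiers can separate them quickly. Degradation applies channel gains
(red 0.55, green 1.0, blue 1.15), contrast compression toward mid-gray
(factor 0.55), Gaussian blur (σ = 1) and additive noise (σ = 4), matching
the qualitative description of underwater optics: red attenuates fastest,
contrast halves, detail blurs. Boxes are measured from the rendered masks,
so labels are tight by construction; `perturb_labels` corrupts a seeded
fraction with multiplicative jitter to emulate low-quality annotation.
Generation is a pure function of (spec, seed).

What the generator does **not** emulate: occlusion layering, lighting
gradients and caustics, camouflage against matched-texture backgrounds,
class-imbalanced long tails, motion blur, or photorealistic water optics.
Tests passing on these scenes establish the correctness and qualitative
behavior of the algorithms (contrast restored, boundaries sharpened, losses
robust to label noise), not field performance on real footage.

## Demo detector

The end-to-end vehicle is deliberately miniature: 64×64 inputs, three
stride-2 stages (8/16/16 channels), an optional DCN residual block as the
deepest stage, optional BiC across the two finest levels, optional
SlimCSPSPPF, SimAM before the head, and a single-scale anchor-free head on
an 8×8 grid (each cell predicts center offsets, sigmoid-bounded sizes,
objectness and class logits). Training: Adam at lr0 = 0.01 (the optimizer
and initial rate kept from the full-scale recipe where they make sense at
this size), batch 8, 250 steps by default, on generated scenes; evaluation
is mAP50 on a held-out generated split with clean labels. Assignment is
center-cell; duplicate centers in one cell keep the last box. A minimal
greedy per-class NMS (IoU 0.45) post-processes predictions. Problem sizes
(64 training scenes, 24 validation scenes, 250 steps) were chosen so the
full pipeline runs in well under a minute per configuration on one CPU
while still clearly separating trained from untrained behavior; the demo
exists to smoke-test block and loss interactions, not to approach
full-scale accuracy.

## Numerical choices and degenerate inputs

- Round-half-up (`floor(x + 0.5)`) for gray-level mappings, avoiding
  banker's-rounding surprises at `.5` boundaries.
- Histograms with zero total raise; constant images map to a constant.
- IoU uses no epsilon in the union (union > 0 for valid boxes); zero-sized
  boxes are rejected rather than smoothed.
- The running-mean denominator of β is floored at 1e-8.
- `maximum`/`minimum` route subgradients to the winning argument; gradient
  checks avoid exact ties and integer offsets.
- Out-of-square label boxes are clipped (annotation tools emit them);
  fully-outside boxes are errors.
- Grayscale images are rejected with an explicit channel-count error; RGBA
  drops alpha with a logged warning.

## Known limitations

- The autodiff engine is single-threaded float64 numpy; it is sized for the
  smoke-scale demo, not for real training workloads.
- The BEM channel is one concrete reading of a loosely specified design;
  alternatives (learned fusion, multiplicative gating) are not explored.
- The exact pyramid wiring of the full RepBi-PAN neck is reproduced only in
  the demo model graph (BiC across the two finest levels, SlimCSPSPPF at
  the deepest); the blocks themselves are standalone and fully tested.
- `exclude_self` SimAM statistics and the `0.5:0.95` AP sweep are
  implemented but are not the defaults anywhere.
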