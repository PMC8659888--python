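# Methods

## Problem and model

`dcnet` implements a densely connected convolutional encoder–decoder for
binary tumor segmentation in 2D T1-weighted MR slices. The clinical problem
it targets — delineating nasopharyngeal-carcinoma gross tumor volume — has
two statistical signatures the architecture is built around: tumor
cross-sections vary in area by orders of magnitude between slices, and the
tumor occupies a tiny fraction of each slice, so foreground/background
classes are severely imbalanced.

The encoder is a DenseNet-style feature extractor: five dense blocks of 12
layers at growth rate 12, joined by channel-compressing transitions
(BN+ReLU+Conv1×1) whose output widths are fixed to (80, 112, 118, 136, 16).
2×2 average pooling after the first two blocks gives feature sizes
(256, 128, 64, 64, 64) for a 256×256 input; later blocks use dilation 2 in
their 3×3 convolutions so receptive fields keep growing after pooling stops.
The final transition is a bare convolution (no BN/ReLU). A PSPNet-style
pyramid pooling module (average pooling at bin sizes 1, 2, 3, 6, 1×1
convolutions, bilinear upsampling, concatenation, one fusing convolution)
injects global context into the deepest 16-channel feature map.

The decoder consumes the pyramid from deep to shallow. Each encoder level is
compressed to 16 channels by a 1×1 convolution (the modified skip
connection); each decoder level bilinearly upsamples the previous decoder
feature to the skip's resolution, concatenates, and fuses with a
BN+ReLU+Conv3×3. Every level has a 1-channel head whose logits are upsampled
to input resolution and passed through a sigmoid, giving side outputs
S1..S5; the deepest level is driven by the pyramid-pooled context alone. The
five side-output logit maps are concatenated and fused by one further
BN+ReLU+Conv into the final segmentation S0. Masks are obtained by
thresholding at 0.5 with ties assigned to foreground.

## Loss

Each output level k is scored by J(S_k) = CE(S_k) + DL(S_k):

* CE is pixel-wise weighted cross entropy
  −[λ ω Σ G log P + Σ (1−G) log(1−P)]/V with V the pixel count of the
  slice and ω = (V − V_P1)/V_P1, the background-to-foreground ratio of the
  *soft* predicted area V_P1 = Σ P. ω is treated as a constant during
  gradient computation (it is a reweighting, not an optimisation target) and
  V_P1 is clamped below at εV. λ defaults to 1.
* DL is a two-class generalized dice loss with inverse-area class weights
  w1 = 1/|G1|, w0 = 1/|G0| and soft intersections; weights are
  ε-stabilised when a class is absent from the slice.

The training objective is the deep-supervision sum Σ_k J(S_k) over S0..S5,
which keeps a non-vanishing gradient at every decoder depth. The single-loss
ablation uses 6·J(S0) so the loss magnitude stays comparable. Losses are
averaged over the slices of a batch; ω is computed per slice.

Interpretations worth flagging: the source text is ambiguous about whether V
is the slice area or the mask area — the slice-area reading is used because
it makes ω exactly the class-balance ratio the weight is said to be for; and
V_P1 uses the soft sum of P rather than a binarised count so the loss stays
smooth.

## Parameter budget and the bottleneck design

The published design fixes growth rate, layers per block, and transition
widths, and states a total of 0.28 M trainable parameters. Plain 3×3
convolutions on the concatenated dense-block inputs are arithmetically
incompatible with that total (they alone cost ≈1.0 M parameters for any
stem width), so dense layers here are DenseNet-B-style bottlenecks:
BN+ReLU+Conv1×1 down to 7 channels, then BN+ReLU+dilated-Conv3×3 producing
the 12 growth channels, dropout (rate 0.2) after each convolution. With a
16-channel stem, 16-channel skip compression and 16-channel decoder fusion
width this gives 275 169 trainable parameters (0.275 M, 1.7% under the
published 0.28 M), while preserving dense connectivity and dilated
receptive-field growth. Biases are omitted wherever a BN follows; the bare
final transition and the 1-channel heads keep biases.

Head biases are initialised to −2 (a background-prior logit,
sigmoid(−2) ≈ 0.12) — the standard prior initialisation for heavily
imbalanced dense prediction — and convolution weights use He-normal
initialisation. Without the prior initialisation the first epochs are spent
un-learning the "half the slice is tumor" state of a neutral sigmoid.

## Training protocol

Stochastic gradient descent (momentum 0.9, no weight decay), learning rate
1e-4, batch size 8. Training proceeds in three equal-length stages: decoder
frozen, encoder frozen, nothing frozen. Freezing disables gradient updates
(and tape construction) for the frozen half; batch-norm running statistics
continue to track activations. Each stage starts with a fresh optimiser and
scheduler at the initial learning rate; within a stage the rate is
multiplied by 0.1 whenever validation DSC has not improved for 10 epochs.
The checkpoint with the best validation DSC across all stages is retained.
An epoch is one pass over the training slices with augmentation re-drawn
each epoch: rotation in ±10°, horizontal flip, and integer translation, each
applied independently with probability 0.5. The translation bound defaults
to ±10 px at 256×256 and should be scaled with the grid (±3 px is used for
64×64 experiments).

Data splits follow the 30-training/10-validation scan design of the source
protocol, with optional cross-validation over independent resplits (4 trials
by default) whose per-trial mean DSCs feed the exact Mann–Whitney U test.

## Metrics

DSC, sensitivity, specificity, precision (PPV), volumetric overlap error and
relative volume difference, all from per-pixel counts. DSC uses the standard
2|P∩G|/(|P|+|G|); a `printed_formula` flag exposes the factor-2-free variant
for audit, since one rendering of the definition omits it while every
reported value is only consistent with the standard form. Degenerate cases
follow declared conventions (empty-vs-empty DSC = 1, VOE = 0; SEN/PPV/SPE
undefined cases return NaN and are excluded from means, with exclusion
counts reported). The Mann–Whitney U test is the exact unpaired two-sided
test, enumerating all C(n+m, n) group assignments with mid-rank handling of
ties; at n = m = 4 complete separation gives p = 2/70 ≈ 0.029.

## Numpy compute engine

The package carries its own compact reverse-mode autodiff engine
(`dcnet.nn`): a Tensor tape over numpy arrays with the op set this network
needs. 1×1 convolutions are channel-mixing BLAS matmuls; 3×3 (possibly
dilated, "same"-padded) convolutions are an im2col gather plus one batched
GEMM; bilinear resizing, 2×2 average pooling and adaptive average pooling
are separable per-axis linear operators, so their backward passes are exact
transposes; batch normalisation uses fused forward/backward kernels
(numba-JIT, with equivalent numpy fallbacks) that recompute rather than
cache the normalised activations. Gradients of every operator are verified
against central finite differences in float64. Training runs in float32;
reductions accumulate in float64. All randomness flows from explicit
`numpy.random.Generator` streams keyed by (seed, purpose), so runs are
bit-reproducible on a fixed platform.

## Synthetic phantoms

The phantom generator emulates the statistical structure of the study data,
which are private: background = low-frequency Gaussian random field (mean
0.40, amplitude 0.12, smoothness 24 px) plus white noise (sd 0.03);
foreground = 1–3 overlapping ellipses with low-order radial Fourier boundary
perturbation, filled at mean intensity 0.75 (sd 0.06), lightly smoothed at
the boundary; area fraction drawn log-uniformly from (0.001, 0.08) of the
slice so tumor scale spans nearly two orders of magnitude. Intensities are
clipped to [0, 1]. The narrow-range case admits one ring of boundary-pixel
slack, since exact fractional areas cannot be rasterised.

What phantoms do not emulate: anatomy (no nasopharynx, skull base or airway
structure), multi-modality contrast, bias fields, partial-volume effects, or
inter-scanner intensity variation. Passing the phantom recovery experiment
therefore demonstrates that the architecture, losses, training protocol and
metrics interoperate correctly and can recover scale-variable lesions from
contrast — not that the published patient-data accuracy is reproduced.

## Scaled experiment sizes

The self-contained experiments run at reduced size so the whole suite
completes on a single CPU: recovery training uses 200 phantom pairs at
64×64 with three stages of 5 epochs each and 50 held-out pairs; unit and
protocol tests use miniature architectures (growth 2–4, 1–2 layers per
block). The full 256×256 architecture is instantiated for all structural
checks (channel/size schedule, parameter count).

A caution about short-horizon training: the protocol's constants (SGD at
lr 1e-4) were chosen for a 300-epoch schedule, so runs hundreds of epochs
shorter are still in the early transient. In that transient the
deep-supervision objective is at a systematic disadvantage on the evaluated
output: it splits a fixed-magnitude gradient across six heads, so the fused
map S0 receives roughly a sixth of the per-path step size that the
single-loss objective (6·J(S0)) concentrates on it. Reduced-budget
comparisons between the two objectives therefore tend to favour the
single-loss variant, and DSC levels reached after tens of epochs are far
below what the full schedule attains; neither observation transfers to the
full 300-epoch protocol.

## Known limitations

* 2D only; volumes are processed slice-wise after RAS+ reorientation,
  min–max normalisation and cubic-spline resampling to 1 mm / 256×256.
* The engine is CPU-bound and single-threaded beyond BLAS; it is sized for
  desk-scale experiments, not full-resolution clinical training runs.
* λ (the CE foreground-weight coefficient) and the augmentation mix
  proportions are not pinned by the source protocol; defaults (λ = 1,
  each transform at probability 0.5) are exposed in configuration.
* Batch-norm statistics in eval mode lag training early in short runs;
  validation DSC in the first epochs understates the network state.
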