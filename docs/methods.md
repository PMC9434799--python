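# Methods

## The model

MM-UNet segments four co-registered MRI modalities (T1, T1c, T2, FLAIR) into
four pixel classes (background, NCR/NET, edema, enhancing tumor). Its premise
is that each modality carries distinct low-level evidence, so each gets an
independent encoder; fusion happens late, by channel concatenation, both at
the network bottom and in every skip connection.

**Encoder.** Per modality, four stages of residual double convolution
(3×3 conv → BatchNorm → ReLU, twice) with a 1×1 convolution projecting the
stage input for the element-wise addition; widths 32/64/128/256; 2×2 max
pooling between stages. The pre-pool feature of each stage forks: one copy is
pooled and descends, the other passes through the hybrid attention block and
feeds the skip connection.

**Hybrid attention block (HAB).** Channel branch: global average, max and
range pooling (range = max − min) over the spatial plane give three C-vectors;
a *shared* two-layer MLP (hidden width C/r) maps each; their sum is squashed
by a sigmoid into the channel mask. Spatial branch: per-pixel mean, max and
range across channels are concatenated into a 3-channel map and reduced by a
single 7×7 convolution plus sigmoid. Default order is channel-first: the
spatial mask is computed on (and applied to) the channel-refined map.
`spatial_first` and `parallel` (both masks from the raw input, applied
jointly) are selectable controls. The parallel combination is an assumption:
the source of that control variant does not define how the two masks combine.

**Dilated convolution block (DCB).** Five parallel channel-preserving
branches — 1×1 conv; 3×3 convs at dilation 1, dilation 3 (padding 3) and
dilation 2 stacked twice (padding 2 each); and global average pooling
broadcast back over the plane — concatenated to 5C channels and reduced to C
by a 1×1 convolution. The block is purely linear internally (the defining
equation lists no activation); the surrounding stages provide nonlinearity.
Impulse-response envelopes are 7×7 for the dilation-3 branch and 9×9 for the
stacked dilation-2 branch, which is the multi-scale receptive-field point of
the block. One DCB per encoder (four copies), placed after the second pooling
(64 channels) by default, or after the fourth as a control.

**Decoder.** The four encoder bottoms are concatenated (1024 channels at
10×10 for a 160 input) and expanded by a plain double convolution to 2048.
Each decoder stage applies a 2×2 stride-2 transposed convolution that halves
the channels, concatenates the four HAB-refined skips of that stage (which
together exactly match the deconvolution width), reduces with a plain double
convolution back to the deconvolution width, and adds the deconvolution
output element-wise — a parameter-free residual, well-typed because the
widths agree. A final 1×1 convolution (3×3 selectable) yields the 4-class
scores at input resolution.

### Decoder width resolution

The published stage table can be read with channel-preserving or
channel-halving deconvolutions. We adopt halving, for three mutually
reinforcing reasons: (1) every number in the published table then appears
naturally, with the "upsampling" rows read as the upsampled-plus-fused
tensor; (2) the described element-level residual addition in the decoder
becomes well-typed without any projection; (3) the published computation
budgets are reproduced: our MAC estimates are 69.8/70.9/69.8/70.9 ×10⁹ for
baseline/+DCB/+HAB/full against printed 69.8/70.9/69.8/71.0, under the
convention of one multiply–accumulate per kernel tap per output element
(dense 2×2 kernel for transposed convolutions; pooling, BatchNorm,
activations and additions uncounted). Parameter budgets land at
110.26/110.95/110.96/111.65 M against printed 110.1/110.8/110.7/111.4 M —
within 0.25 % but not to the printed 0.1 M. No realization closes that gap:
the printed increments (+0.6 M attention, +0.7 M dilated block) are mutually
inconsistent with any shared-MLP attention block at r = 1 (+0.70 M) and any
channel-preserving dilated block (+0.69 M, or +0.71 M with a convolution on
the pooling branch); reading the table as channel-preserving deconvolutions
instead moves every count by ≥ −0.3/+1.6 M and inflates the MAC estimate to
≈ 101 ×10⁹.

The attention MLP uses reduction r = 1 (no hidden-width reduction) with
biases; this is the only realization whose parameter increment is near the
printed one (conventional r = 16 would add only ~0.05 M). BatchNorm uses
eps = 1e-5, momentum = 0.1, affine scale/shift counted as learnable.
Initialization is Kaiming fan-in normal for all convolutions and linear
layers, unit BatchNorm scale, zero biases, drawn from a generator seeded by
the config seed.

## Loss

L = α·L_Dice + β·L_Focal per class plane, averaged over the four classes
(background included by default, switchable), computed per image and averaged
over the batch. Defaults α = 0.1, β = 0.9. The Dice term uses smoothing
ε = 1e-5 (unstated in the source; the canonical guard), the focal term
uses γ = 2 (unstated; the canonical setting) and clips probabilities to
[1e-7, 1−1e-7] before logs, which keeps gradients finite even at saturated
softmax outputs. A Dice-only mode (α = 1, β = 0) mirrors the loss-function
control experiment.

## Evaluation

Regions from the dense labels {0,1,2,3}: WT = {1,2,3}, TC = {1,3}, ET = {3}.
DSC = 2TP/(2TP+FP+FN); when both masks are empty in a non-ET region the score
is defined as 1.0 (correctly predicted absence; only the ET case is
legislated by the protocol). HD95 extracts boundary pixels (set pixels with
an unset 4-neighbor), computes exact Euclidean nearest-neighbor distances
between the two boundaries (k-d tree), takes the 95th percentile of each
directed set (linear-interpolation percentile) and symmetrizes with the max;
a pooled-percentile variant sits behind a flag. HD95 against or from an empty
mask is recorded as undefined-with-reason and excluded from means, never
silently dropped or zeroed. The enhancing special rule: if ground-truth ET is
empty the ET Dice is 0 when the prediction has enhancing pixels and 1 when it
does not, flagged special; aggregation removes flagged values, then averages
per region, and the overall means are the arithmetic means of the three
per-region means. Scoring operates on whatever grid it is given (2-D slices
here); 3-D volume reassembly is out of scope.

## Preprocessing

Center crop to (160,160,128) — the stated source size conflicts with the
standard grid for this data, so the reader accepts any source at least as
large and records the original shape. Axial slices along the last axis;
labels remapped {0,1,2,4} → {0,1,2,3}. Slice policy: `tumor-bearing`
(training default) or `all` (inference). Intensities: per-modality z-score
over nonzero voxels with zero background preserved (the source does not
state a normalization; this is the field convention, switchable off).

## Phantom generator

Each case is four 2-D images plus labels on one grid: an elliptical brain of
normal tissue on a zero background, containing nested tumor ellipses —
enhancing core, necrotic shell, edema shell — so ET ⊆ TC ⊆ WT holds by
construction. Per-tissue mean intensities come from a contrast table whose
defaults make the enhancing core brightest in T1c and the edema extent
brightest in FLAIR; Gaussian noise (sd 5 at default contrast ~100–200) is
added wherever tissue is present. Dataset generation jitters center, radii,
contrast and ellipse axis ratio per case, resampling draws that would break
nesting, and forces an exact fraction of cases (default 25 %) to have an
empty enhancing region so the special scoring rule is exercised. Defaults:
160×160 grid, radii (30, 18, 8) px scaled with grid size. Everything is
bit-reproducible from the seed.

What the phantom does *not* emulate: 3-D anatomy, bias fields, partial
voluming, heterogeneous texture, inter-rater label noise, or realistic tumor
shape. Consequently a perfect training score on phantoms demonstrates that
the architecture, gradients, optimizer and metrics are wired correctly and
can fit class-dependent multimodal contrast — not that the model segments
real gliomas at any particular accuracy.

## Training

Adam (β₁ = 0.9, β₂ = 0.999, eps = 1e-8), batch size 8, learning rate 1e-5,
15 epochs — the reference settings are the defaults. No augmentation,
scheduler, weight decay or early stopping (none are described). Shuffling is
a seeded per-epoch permutation; runs are bit-reproducible given the seed.

**Desk-scale overfit protocol.** The package's learning sanity check trains
the full architecture at base width 8 on eight 32×32 phantom slices
(batch 8 = full-batch) with Adam at 1e-3 for 250 steps, then evaluates on
the training slices. These sizes are the package's own protocol choice for a
single-CPU NumPy run: at reference scale (width 32, 160×160) a forward pass
costs ~7×10¹⁰ MACs, and at learning rate 1e-5 a few hundred steps cannot
move randomly initialized weights appreciably (the reference rate is tuned
for tens of thousands of steps). The reduced protocol reaches mean
foreground Dice ≥ 0.90 (in practice 1.0) with a monotone loss trend. A
single full-scale 160×160 forward+backward pass is separately exercised in
the unit tests (~20 s).

## Numerical choices

float32 parameters and activations; float64 in gradient-check tests.
Convolutions are stride-1 sliding-window tensordot contractions; the 2×2
stride-2 transposed convolution maps each input pixel to a disjoint 2×2
output block. Max pooling routes gradients to the first maximum on ties;
the max/min channel poolings route to all tied extrema. Softmax is
max-shifted. The loss is computed per class plane in a Python loop — clear
and fast enough at the class count of four.

## Known limitations

2-D slices only; no 3-D convolutions, no test-time augmentation or
ensembling; no bias-field or registration handling (inputs are assumed
co-registered and skull-stripped); the NumPy engine is single-threaded
BLAS-bound and meant for desk-scale runs, not full-dataset training; MAC
estimates are convention-dependent diagnostics, not hardware predictions.
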