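# Methods

`gliomaseg` implements a complete, desk-scale 3D brain-tumor
segmentation pipeline for multi-modal MRI in the BraTS case layout:
a per-slice mathematical enhancement stage (wavelet decomposition,
deflation PCA, covariance matched filter), a trainable 3D attention
U-Net, a BraTS-style evaluation battery, and a synthetic phantom
generator that lets every stage run end to end with known ground truth
and no external data.

## Data model

A case is four co-registered channels — Flair, T1, T1ce, T2 — stored
as `(4, X, Y, Z)` float arrays with voxel spacing in mm and a 4x4
voxel-to-world affine, read and written as NIfTI-1 via nibabel. Label
volumes carry the BraTS vocabulary `{1, 2, 4}` by default
(1 = necrotic core, 2 = edema, 4 = enhancing tumor), with a config
switch to the `{1, 3, 4}` vocabulary used by some annotation sets.
Evaluation regions are the standard nested unions: enhancing tumor
ET = {4}, tumor core TC = {1, 4}, whole tumor WT = all tumor labels,
so WT ⊇ TC ⊇ ET always holds. Arrays are indexed `(x, y, z)`; axial
slices are planes of fixed `z`, the BraTS acquisition plane.

## Slice enhancement

**Wavelets.** Each axial slice is decomposed with a separable 2D DWT
into an approximation band `W_φ` at the coarsest scale and detail
triples `W_ψ^{H,V,D}` per scale. The default wavelet is Haar with one
level; both are configurable. We use orthonormal filters in
periodization mode, which makes the transform an isometry (coefficient
energy equals slice energy) and the forward/inverse pair exact to
machine precision; odd slice extents are padded to even internally and
cropped on reconstruction, which is still exact. Normalization
constants are absorbed into the orthonormal filter bank — this is the
unique normalization for which decomposition and reconstruction are
mutual inverses.

**Deflation PCA.** Optionally, the detail coefficients of a channel's
slice stack (rows = slices, columns = vectorized detail bands, a
choice made because the slice stack is the only natural sample axis at
inference time) are compressed to `k` components. Components are found
*sequentially*: `w_i` maximizes `‖X̂_i w‖²` over unit vectors on the
deflated matrix `X̂_i = X_c − Σ_{s<i} X_c w_s w_sᵀ`. Each
maximization is a leading-eigenvector problem solved by power
iteration (tolerance 1e-14 on the direction, at most 5000 iterations)
followed by three Rayleigh-quotient iterations, which converge
cubically and pin the direction to ~1e-15. The procedure is verified
against a dense eigendecomposition of `X_cᵀX_c` in the tests; the
component-score covariance `Q[j,k] = (X w_j)ᵀ(X w_k) = λ_k w_jᵀw_k`
is asserted diagonal with the eigenvalues on the diagonal.
Zero-variance input returns an arbitrary orthonormal basis with zero
eigenvalues and a warning.

**Covariance matched filter.** Let `v` be the flattened 3×3×3
neighborhood of a voxel (patch shape configurable) and
`R_v = E[(v − v̄)(v − v̄)ᵀ]` the covariance of neighborhoods drawn
from a reference region, with mean vector `v̄`. For a signal `s` in
noise with covariance `R_v`, no linear filter `h` exceeds the output
SNR bound

    (hᵀs)² / (hᵀ R_v h)  ≤  sᵀ R_v⁻¹ s,

with equality iff `h ∝ R_v⁻¹ s` (Cauchy–Schwarz in the whitened
domain). The enhancement map scores every voxel with this attained
energy, `E_p = sᵀ (R_v + εI)⁻¹ s`, where `s = v − v̄` is the voxel's
own neighborhood deviation ("self" mode) or, in "template" mode, a
fixed template is matched instead. Conjugate transposition reduces to
transposition because MRI magnitude images are real.

Numerical choices:

- `s` deviates from the *model's* mean `v̄`, not from the patch's own
  mean. Per-patch centering would annihilate flat lesion interiors and
  leave only edges detectable; deviation from `v̄` keeps a uniformly
  shifted lesion anomalous while remaining exactly invariant to a
  constant intensity offset of the channel (the offset moves `v̄`
  equally).
- Diagonal loading `ε = 1e-6 · trace(R_v)/p` (floored at 1e-12 for
  zero-variance data, escalated tenfold until a Cholesky factorization
  succeeds) guarantees invertibility; flat regions otherwise make
  `R_v` singular.
- The reference region defaults to a volume-wide subsample of at most
  4096 neighborhoods — the classic anomaly-detection choice: a lesion
  occupying a few percent of the volume barely perturbs `R_v` and so
  scores high, whereas a reference restricted to the immediately
  preceding axial slab treats any structure extended across slices as
  background (measured: no WT contrast on phantoms). The slab-local
  mode is available as `per_slab_covariance=True`. Covariance is always
  estimated from unpadded neighborhoods; reflect padding is used only
  for scoring, because padded slabs contain duplicated planes that
  make the sample covariance exactly singular.
- The candidate-voxel gate is a percentile threshold on `E_p` (default
  95th), configurable.

The enhanced volume itself is the wavelet-reconstructed (optionally
PCA-compressed) 4-channel stack; the energy map, averaged over the
configured channels, is appended as a fifth network input channel.
With PCA disabled the wavelet stage is an exact identity, and with
`covariance="identity"` the whole stage reduces to the input plus a
squared-norm map — a useful null configuration for testing.

## Reference convolution layer and the autodiff engine

The single-channel, stride-1, valid 3D convolution layer is written
twice, deliberately:

1. `conv3d_ref` implements the forward pass
   `x_ijk = Σ_abc ω_abc y_(i+a)(j+b)(k+c)` (cross-correlation index
   convention, no kernel flip), the weight gradient
   `∂E/∂ω_abc = Σ_ijk ∂E/∂x_ijk · y_(i+a)(j+b)(k+c)`, the activation
   chain `∂E/∂x = ∂E/∂y · σ'(x)`, and the input gradient as the full
   correlation with the index-reversed kernel — each directly from the
   layer equations.
2. `autodiff` is a small tape-based reverse-mode engine on numpy
   (broadcast arithmetic, sigmoid/ReLU, reductions, concatenation,
   same/valid multi-channel conv3d via im2col + BLAS, 2× max-pooling,
   2× nearest-neighbor upsampling, instance normalization, Adam). The
   trainable network runs on this engine.

`gradient_check` compares the two against each other and against
central finite differences (step 1e-6) on ≤ 8³ inputs; agreement is
~1e-9 relative against finite differences and ~1e-15 against the
engine. The adjoint identity
`⟨conv(y, ω), g⟩ = ⟨y, backward_input(g, ω)⟩` is asserted separately.

## 3D attention U-Net

Encoder/decoder in a U topology. Each level is two 3×3×3 same-padded
convolutions with instance normalization and ReLU (convolutions before
a normalization carry no bias — it would be normalized away and its
gradient would be identically zero); levels are connected by 2×
max-pooling and 2× nearest-neighbor upsampling followed by a
channel-halving convolution. Every decoder level concatenates the
matching encoder skip, applies the attention module, then convolves.
A final 1×1×1 convolution maps to class scores; per-voxel softmax and
argmax produce labels.

The attention module combines two sigmoid-gated branches computed from
the feature block `F` with `C` channels: a *spatial* gate (1×1×1
convolution across channels → one `X×Y×Z` map) and a *channel* gate
(global average pooling → dense `C→C` map → `C`-vector), joined
multiplicatively and added back through a bypass connection:

    out = F + F ⊙ spatial ⊙ channel.

The additive identity path keeps gradients flowing when gates
saturate. Because a sigmoid never reaches 0 exactly, the exact
bypass-identity property is stated at the combination level: for zero
gate maps, `apply_attention(F, 0, 0) == F` bitwise; the module
separates map computation from the combination so this path is
directly testable.

Defaults are depth 3, 8 base filters, instance normalization, ReLU,
nearest-neighbor upsampling, and 5 input channels (4 enhanced
modalities + energy map; a config switch drops the energy channel).
These sizes are the package's own desk-scale choice — the network
trains in minutes on one CPU core at these settings — and every one is
config-exposed; deeper/wider configurations are constructed by the
same code. Parameter count is a deterministic function of the config
and is asserted against an independent layer-by-layer count in the
tests.

## Training and inference

Training is patch-based: each step samples one case, crops a 32³
patch (90% of crops centered on a random tumor voxel, the rest
uniform), applies random axis flips, and takes one Adam step
(lr 1e-3) on the loss *soft-Dice + cross-entropy* with equal weights
— the Dice term counters the extreme foreground/background imbalance,
the cross-entropy term smooths early optimization. Runs are exactly
reproducible for a given seed; a NaN loss aborts with a diagnostic.
When a validation set is given, whole volumes are segmented
periodically and the weights with the best validation WT Dice are
restored at the end.

Inference is sliding-window with 50% overlap and probability
averaging. The window defaults to the training patch size (32³): the
instance-norm statistics at inference then match those seen in
training; full-volume windows on a patch-trained network measurably
degrade Dice (0.84 vs 0.97 WT on an overfit phantom). Averaging over
overlapping windows is invariant for constant predictors, which is
asserted as a test.

## Phantoms

`generate_phantom` builds a smooth ellipsoidal brain (semi-axes 0.44
of the volume extent, tissue intensity 100) carrying three nested
tumor ellipsoids — edema (outer semi-axes drawn from 10–16 voxels at
the default 64³ size), core (0.55–0.7 of edema), enhancing rim
(0.5–0.7 of core) — at a random interior center, so subregion nesting
holds by construction. Per-modality intensities follow the
qualitative BraTS pattern: edema bright on Flair/T2, enhancing bright
on T1ce, core dark on T1. The intensity field is smoothed with a
σ = 1 voxel Gaussian and white Gaussian noise of σ = 5 (5% of the
tissue intensity scale) is added last. Each case is fully determined
by `(seed, case_index)`; `generate_dataset` writes BraTS-layout case
directories plus a manifest for exact regeneration.

What the phantoms do *not* model: MR physics (bias fields, partial
volume, Rician noise), lesion texture and infiltrative boundaries,
anatomy, multi-focal disease, or registration error. Passing the
recovery tests therefore demonstrates that the pipeline is wired
correctly and can learn a strongly contrasted lesion — not that it
reaches clinical accuracy on real BraTS data.

## Evaluation

Per region (ET/WT/TC): Dice `2|A∩B|/(|A|+|B|)` with the both-empty
convention Dice = 1; Hausdorff distance as HD95 — the maximum over
both directions of the 95th percentile of surface-to-surface
distances in mm, computed via Euclidean distance transforms with
anisotropic spacing (the classical max-Hausdorff is the
`percentile=100` flag); sensitivity `TP/(TP+FN)` and specificity
`TN/(TN+FP)` with an explicit 0-with-warning fallback for empty
denominators. One region empty and the other not returns a configured
Hausdorff penalty (default: the image diagonal in mm) with a warning;
both conventions follow common BraTS evaluation practice. Pixel-level
accuracy/precision/recall/F1 and the 2×2 confusion matrix are
computed on the binary tumor/non-tumor task (any nonzero label =
tumor). A dataset aggregator reports mean/stddev/median per metric
per region, invariant to case order.

## Problem sizes used by the acceptance run

The acceptance script exercises: exact pixel accounting at 809×974;
100 random slices for reconstruction; 50 random matrices (up to
50×20) for the PCA equivalence; 500 random filters for the SNR bound;
gradient checks at 6³/3³ for three activations; training on 8
phantoms of 64³ for 300 steps with 2 held-out cases, plus a 400-step
overfit of a single 48³ phantom. These sizes are chosen so the whole
run completes in minutes on one CPU core while still exercising every
stage end to end.

## Known limitations

- The network trains on a numpy reverse-mode engine: single-threaded,
  no GPU, so BraTS-scale training (240×240×155, hundreds of cases) is
  out of reach; the architecture itself scales by config.
- The matched filter assumes a globally stationary background within
  a channel; slowly varying intensity (bias fields) would inflate the
  reference covariance. The slab-local mode trades this for blindness
  to structures extended along `z`.
- HD95 surface extraction uses 6-connectivity erosion on the voxel
  grid; sub-voxel surfaces are not modeled.
- The phantom generator is geometric, not physical (see above).
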