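# Methods

## The model

`davsnet` implements a densely aggregating encoder–decoder network for
semantic segmentation of retinal blood vessels in fundus photographs.
Every pixel is classified as vessel or background, which is what makes
the approach sensitive to minor vessels only a few pixels wide — the
structures that matter clinically, because diabetic retinopathy swells
or creates vessels while hypertensive retinopathy shrinks them.

The architecture is small by design (about 2.57 M trainable parameters
in total):

* **Encoder** — three dense blocks. Block *i* applies Conv-A (3×3) →
  BN → ReLU producing `F_i'`, Conv-B (3×3) producing `K(F_i')`, and
  aggregates them depth-wise, `A_i¹ = K(F_i') * F_i'` (`*` denotes
  channel concatenation). A BN → ReLU → 1×1 bottleneck reduces the
  doubled channel count, and a 2×2/2 max-pool halves the resolution
  while retaining the argmax index of each window. Channel plan:
  64/64 → cat 128 → 64; 128/128 → cat 256 → 128; 256/256 → cat 512 → 256.
  A 640×640 input reaches the bottom of the encoder at 80×80×256.
* **Decoder** — the mirror image. Each block starts with a max-unpool
  driven by the indices of the mirrored encoder pool (values return to
  their original spatial positions; everywhere else is zero), applies
  Conv-A/Conv-B, and concatenates *three* features,
  `A_i² = K(U_i') * U_i' * F_i'`: the block's own two convolutions plus
  the mirrored encoder block's Conv-A activation carried by an outer
  dense path. These outer paths hand early edge information directly to
  the late decoder stages. Channel plan: 256/128 → cat 640 → 128;
  128/64 → cat 320 → 64; 64/2 → cat 130 → 2. The final 1×1 bottleneck
  doubles as the class-mask layer (2 channels, vessel/background),
  followed by a per-pixel softmax and argmax.

Structural tallies used as validator constraints: 12 3×3 convolutions,
6 1×1 bottlenecks, 6 dense blocks, 3 pool/unpool pairs.

### The symbolic graph and the reference audit

`davsnet.graph` describes the network declaratively and, with no
numerical runtime involved, propagates shapes and counts parameters
(convolution: `kh·kw·C_in·C_out` weights + `C_out` biases; batch norm:
learnable scale+shift `2C` only — running statistics are not trainable).
`audit_against_reference` compares the computed audit with the published
per-layer table transcribed verbatim. Two printed cells are
arithmetically inconsistent with their own neighbours and are flagged
`RECONCILED`, never silently corrected:

* the second encoder bottleneck row is printed as a duplicate of the
  first ("8256 + 128"), although the adjacent pool output (160×160×128)
  and the following block's printed 295,168 parameters both force a
  256→128 bottleneck — reconciled to 32,896 + 256;
* the filters cell of the deepest decoder's second convolution prints
  64, although its own parameter cell (295,040) and the concatenation
  depth 640 = 256+128+256 force 128 filters.

Label and output-shape cells that disagree with their own row's filter
count (e.g. decoder rows printed with encoder labels) are annotated on
otherwise `MATCH`ing rows. Every arithmetically self-consistent
parameter cell is reproduced exactly.

### Design choices where the layer ordering was open

The per-layer marker in the reference table places ReLU and BN "after"
the marked convolutions without fixing their mutual order. This package
uses conv → BN → ReLU throughout, and additionally BN → ReLU between
every concatenation and its bottleneck (the bottleneck is described as
acting after BN and ReLU). The post-concatenation BN layers have no
printed parameter cell; the audit reports them as unprinted rather than
comparing them. The final bottleneck is likewise followed by BN → ReLU
before the softmax; its BN contributes the printed "+4".

## Executable runtime

No deep-learning framework is used: the graph is interpreted directly
in NumPy. Convolutions run as im2col window views contracted with BLAS
(`same` padding, stride 1 — forced by the table's size-preserving
outputs); pooling is 2×2 stride 2 with ties broken to the first
(row-major) position so index transfer is deterministic. Forward and
backward passes share the single graph definition, and the backward
pass is verified against central finite differences (relative tolerance
1e-4, with an absolute floor of 1e-8 for near-zero gradients — conv
biases feeding a train-mode BN have exactly zero effect, so both
estimates are numerical noise there).

Numerical details: activations are float32 by default (float64
available, used for gradient checking); BN uses ε = 1e-5 and running
statistics with momentum 0.9 for inference, making inference bitwise
deterministic; weights are fan-in-scaled He-normal from a seed (the
original work trained "from scratch" without saying how, so a standard
reproducible scheme was chosen); softmax is max-shifted for stability.
Checkpoints store the graph description plus every named array and
round-trip bit-exactly.

## Training

The objective is weighted cross-entropy with median frequency
balancing: `freq_c` is the pixel count of class *c* divided by the total
pixels of images where *c* occurs, and `weight_c = median(freqs)/freq_c`
(the median of two frequencies is their midpoint). With vessels at
~7 % of pixels this weights vessel errors ≈ 7× background errors. A
floor of 1e-12 inside the log keeps the loss finite; training aborts
with a diagnostic if the loss still goes non-finite.

The optimiser is Adam at a constant learning rate 1e-3 with first-moment
decay 0.9 and mini-batches of 10 images; the quoted "exponential decay
rate of 0.9" is read as the first-moment coefficient (its conventional
description), with the second moment at the usual 0.999. The epoch
count is left to the caller — no default is claimed. Pixels outside the
FOV can optionally be excluded from the loss
(`restrict_loss_to_fov`); the default includes all pixels, the simpler
reading, since the loss masking behaviour is not specified anywhere.

Leave-one-out splitting returns, for *n* samples, *n* folds training on
*n−1* with each sample held out exactly once, in input order.

## Augmentation

Rotations in 1-degree steps (masks rotated nearest-neighbour so they
stay binary, images bilinearly, corners filled with 0) and
multiplicative brightness perturbation clipped to the valid intensity
range, with factors drawn uniformly from an interval that must straddle
1 (default [0.8, 1.2]; no range is published, so a conservative,
configurable one was chosen). The preset "360 rotations + 20 brightness
variants per image" reproduces the quoted total of 7,600 variants from
a 20-image training set; the generator always reports its own count
rather than asserting a published one, because the exact recipe behind
the quoted totals is not derivable unambiguously.

## Evaluation

All metrics are restricted to the FOV (stated explicitly for accuracy;
adopted for every metric here, the stricter reading). Se, Sp, Acc are
the exact count ratios; FPR = 1 − Sp; zero denominators yield NaN
rather than a silent 0. ROC-AUC is trapezoidal over all distinct score
thresholds, which equals Mann–Whitney concordance with ties counted 0.5
(ties handling is unspecified in the source; 0.5 is the standard
choice). The PR area uses step-wise (average-precision) integration —
trapezoidal PR integration would not satisfy the no-skill baseline
AUCPR = prevalence. Sets are summarised both per image and pooled by
summing confusion counts (and pooling scores for curve areas), since
the published tables do not state their aggregation.

## Synthetic data

The generator emulates the features of fundus photographs the network
and metrics actually depend on: a bright circular FOV (radius 46 % of
the short side) on a dark background; a vascular tree grown as a
recursive binary branching process from one or two root stems at the
FOV edge (segment walks with smooth direction jitter of σ = 0.035
rad/px; children offset within ±40°; caliber starting at 1.2 % of the
short side — about the major-vessel width of real images — and
multiplied by 0.75 per generation until it falls below one pixel);
vessels rendered darker than the orange, green-dominant background
(contrast 0.35); radial illumination falloff (amplitude 0.25); smooth
background texture and additive Gaussian noise (σ = 0.03). Masks are
exact by construction, vessels are clipped to the FOV, and samples are
bit-reproducible from their seed. The vessel fraction is constrained to
3–15 % of the FOV (the sparsity range of real vasculature); a draw
outside the band retries with rescaled caliber and raises after a
bounded number of attempts.

What the generator does *not* emulate: pathology (lesions, exudates),
the optic disc and macula, inter-image colour variation, JPEG-like
artefacts, and the fine anastomotic structure of real capillary beds.
Tests passing on synthetic data therefore demonstrate that the
architecture, objective, protocol and metrics are implemented correctly
and that the network can learn vessel-like structure — not that it
reaches any particular accuracy on real fundus benchmarks, which would
require the external datasets and GPU-scale training.

## Problem sizes used in the test suite

The symbolic audit runs at the canonical 640×640×3. Executable-network
tests run at 8–64 px inputs, where the architecture is unchanged (the
channel plan does not depend on resolution). The convergence check
trains on 4 synthetic 64×64 images with full-batch Adam at the default
optimiser settings and stops once in-FOV training accuracy exceeds
0.95 (cap 300 iterations); it typically converges in well under 100
iterations. These sizes keep the whole suite CPU-friendly while
exercising every code path at canonical channel widths.

## Known limitations

* Single-threaded NumPy convolutions are orders of magnitude slower
  than GPU training; the package targets correctness, auditability and
  small-scale experiments, not benchmark-scale training.
* Only binary (vessel/background) segmentation is supported.
* The ReLU preceding the softmax (as the reference table marks it)
  clips both class logits at 0; the preceding BN keeps activations
  centred so training works, but pixels with both logits clipped are
  ties and predicted background.
* The FOV synthesiser (for datasets shipping no FOV masks) assumes a
  single bright, roughly convex imaged region.
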