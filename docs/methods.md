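# Methods

## Problem and scope

The package targets fine-grain binary segmentation of intervertebral discs
in 2-D mid-sagittal MR-like images. Whole-area overlap scores hide exactly
the failure mode that matters clinically — sloppy delineation of the disc
margin — so the toolkit pairs four encoder–decoder networks with an
evaluation suite that isolates boundary accuracy: Dice over the whole
region, Dice restricted to 1- and 2-pixel boundary bands, and the modified
Hausdorff distance (MHD) in millimetres.

Everything runs on CPU. The network layers (convolution, batch
normalization, max-pooling, nearest up-sampling) are implemented directly
on NumPy with explicit reverse-mode differentiation and an Adam optimizer;
gradient correctness is pinned to central finite differences in the test
suite. This keeps the architecture mechanics — the pooling paths, shortcut
connections and cascade fusion that are the point of the package — fully
inspectable.

## The four networks

All variants share one skeleton: five down-sampling stages (input
256×256×1, or 64×64 in the small preset), a bottleneck, a mirrored decoder
with skip concatenations, and a 1×1 sigmoid output emitting a per-pixel
foreground probability. ReLU + batch normalization follow every
convolution except the output. Padding is "same" everywhere, so skips
concatenate without cropping. Weights are He-normal from a seeded
generator.

- **Conventional U-net** — three 3×3 convolutions per encoder stage, two in
  the bottleneck, 2×2 max-pooling; decoder stages up-sample (nearest ×2 +
  3×3 convolution) and apply three 3×3 convolutions.
- **Dilated U-net** — each max-pool is replaced by a stride-2 3×3
  convolution, preceded by a dilated block: three parallel 3×3 branches at
  dilation rates 1, 2 and 3 sharing the input, concatenated, then a
  spatial-size-preserving 3×3 tail convolution. Multi-rate context enters
  before every resolution drop.
- **Cascaded U-net** — the conventional skeleton plus back-end guidance: a
  separately trained conventional U-net's probability map is concatenated
  with the final decoder features and digested by four 3×3 convolutions
  before the output. The first-stage net stays frozen during stage-2
  training.
- **BSU-net** — three changes at once:
  1. *BSU-pooling* replaces each max-pool with three parallel paths — 2×2
     max-pool followed by a channel-matching 1×1; a stride-2 3×3; and a 1×1
     followed by a stride-2 3×3 — concatenated and fused by a 1×1. The
     convolutional paths retain the neighborhood information that
     max-pooling alone discards.
  2. *Residual blocks* replace plain convolution stages: an entry 1×1
     matches channels, two 3×3 convolutions learn the residual S(x), an
     identity shortcut adds the entry output back (H(x) = S(x) + x, so the
     Jacobian of the block core is the residual Jacobian plus the
     identity), and an exit 1×1 re-mixes channels. With the body at zero
     the post-addition activation equals the entry output exactly; the
     test suite asserts this bit-for-bit.
  3. *Back-end cascade fusion* as in the cascaded U-net, but with a 1×1
     reduce after the guidance concat and three 3×3 head convolutions. Its
     decoder up-path uses 1×1 (not 3×3) post-upsample convolutions — part
     of the variant's parameter economy; spatial mixing is supplied by the
     residual bodies.

Guidance injection at the *front* of the encoder (instead of the back-end)
is retained as an explicit negative-control topology
(`front_end_guidance=True`), because detail present in the stage-1 map
would otherwise be destroyed by the second encoder's own pooling.

### Reference configurations and the counting convention

The published description fixes the layer *totals* of each variant but not
the per-stage channel widths, so the shipped reference configurations were
frozen by a constraint search over the skeleton above. Counting
convention: every 1×1 or 3×3 convolution counts as a convolutional layer —
including stride-2, dilated and post-upsample convolutions — while pooling
and up-sampling themselves (parameter-free) do not; trainable parameters
sum convolution kernels, biases, and batch-norm scale/shift (2 per
channel). Under this convention the frozen stage-width schedules

| variant        | stage widths                     | conv layers      | parameters |
|----------------|----------------------------------|------------------|------------|
| unet           | 50, 100, 200, 346, 682, 1037     | 38 (37+1)        | 62,803,650 |
| dilated_unet   | 46, 92, 184, 364, 512, 781       | 63 (62+1)        | 69,048,584 |
| cascaded_unet  | 45, 90, 180, 281, 649, 1287      | 42 (41+1)        | 63,912,898 |
| bsu_net        | 52, 104, 208, 354, 469, 870      | 79 (35 3×3 + 44 1×1) | 53,740,674 |

reproduce all four published parameter totals and all published layer
counts simultaneously and exactly (`summarize_network` recomputes them
from the built layer graph; `scripts/acceptance.py` re-derives them from
scratch). Widths are per-variant because the totals are mutually
incompatible with a single shared schedule; each schedule is the exact
solution of the corresponding parameter-count polynomial, selected among
the exact solutions so that base widths are comparable across variants
(45–52) and width-scaled desk runs give every variant similar first-stage
capacity. The
`width_multiplier` knob scales every stage width (rounded, minimum 1) for
desk-scale work; conv-kernel parameters scale ≈ quadratically, which the
suite checks as the ~4× law at half width.

## Training

Adam at learning rate 1e-3, pixel-wise binary cross-entropy on the sigmoid
map, batch size 4, inputs min-max normalized to [0, 1] (bilinear resize to
the target matrix when needed; masks nearest-neighbour + re-binarized at
0.5). Binarization threshold 0.5 at prediction. Cascade variants train
sequentially: stage 1 to completion with identical hyperparameters, then
frozen while stage 2 consumes its probability maps. Loss that turns
non-finite aborts with diagnostics. Full-scale settings (256×256, 200
epochs) are retained as `PAPER_PRESET`; the `SMALL_PRESET` used throughout
the tests is 64×64 phantoms, width_multiplier 1/8, 50 epochs, 20
training / 5 test images — sized so a complete four-variant comparison
runs in minutes on one CPU core. Training is bit-reproducible for a fixed
seed and thread count (single-threaded BLAS reductions are deterministic;
the seed drives initialization and batch shuffling).

## Phantom generator

Each phantom is a vertical stack of elliptical discs interleaved with
brighter rectangular vertebral-body surrogates on a darker background, at
1.5 mm nominal pixel spacing. The generator parameterizes exactly the
three difficulties the real task poses: (1) shapes are rotated (±15° by
default) and radially deformed by a smooth 2–4-harmonic Fourier
perturbation of the ellipse radius (amplitude `deformation_amp`, default
0.12 — smooth, disc-like irregularity without sharp artifacts); (2) the
disc/background intensity step is `boundary_contrast` (default 0.35,
scaled by 0.55 intensity units at full contrast) and can be made
arbitrarily low; (3) intensity inside objects is made non-uniform by a
smooth multiplicative cosine bias field (amplitude 0.25) plus additive
Gaussian noise (σ = 0.04). Gaussian rather than Rician noise is used: at
these contrast levels the distinction is immaterial for benchmarking and
keeps the generator dependency-free. Corruptions touch the image only —
the mask is pure geometry — and intensities are clipped to [0, 1] last.

Patients own 1–3 slices sharing one geometry seed (adjacent mid-sagittal
slices of one spine) but independently corrupted; the default cohort is 20
patients / 25 slices. Patient-exclusive k-fold splits shuffle patients
with the seed and assign greedily (largest patient first) to balance
per-fold image counts; with the default cohort every fold holds exactly 5
test and 20 training images.

What the phantoms do *not* emulate: MR physics (T2 contrast, partial
volume), anatomical variation beyond affine + low-order deformation,
pathology, and 3-D context. Passing the desk-scale benchmark therefore
demonstrates that the mechanisms train and order as described on
controlled geometry — not clinical-grade accuracy on real spines.

## Evaluation

Boundary bands are mask minus its t-fold morphological erosion with the
full 3×3 (8-connected) structuring element, so a 1-pixel band is closed
around diagonal steps. MHD uses the 1-pixel boundary pixel centres as
point sets — it is a boundary-accuracy measure — and returns
max(d(A,B), d(B,A)) of the directed mean nearest-neighbour distances,
scaled by the pixel spacing (1.5 mm default, configurable). All discs pool
into one foreground class per image; metrics are computed once per image.
Empty-vs-empty Dice and any-empty MHD raise rather than coerce to 0 or 1 —
silent defaults would skew cohort means. Cohort tables report mean and
sample SD (n−1), Dice in percent, MHD in mm; a single-case cohort reports
SD 0 with an explicit flag. Paired comparisons use the two-sided paired
t-test with tiers ns / * / ** / *** at p = 0.05 / 0.01 / 0.001 and no
multiple-testing correction.

## Numerical choices and edge cases

- float32 throughout the networks; metrics in float64.
- "Same" padding splits any odd total pad with the extra pixel at the
  bottom/right (stride-2 3×3 pads (0,1)).
- Max-pool ties resolve to the first maximum (argmax order), matching the
  gradient routing.
- Batch-norm: ε = 1e-5, momentum 0.1, running stats used in eval mode.
- BCE clips probabilities to [1e-7, 1 − 1e-7].
- BSU-pooling and 2×2 max-pooling require even spatial dims and raise a
  shape error otherwise; network inputs must be divisible by 2^depth.
- `summarize_network` is a pure function of the config (weights are
  counted, never read), so repeated calls agree exactly.

## Known limitations

- The desk-scale benchmark is a mechanism check; absolute Dice/MHD values
  at 64×64 with 1/8-width networks are not comparable to full-scale
  results on real MR data.
- Joint (rather than sequential) cascade training is not implemented.
- Single foreground class only; no per-disc-level labelling, no 3-D.
- The reference width schedules are exact solutions to the published
  totals under the documented convention, not a claim about the original
  implementation's internal layout, which the source text does not fully
  specify.
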