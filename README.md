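# bsunet

Boundary-specific U-net (BSU-net) toolkit for fine-grain segmentation of
intervertebral discs in 2-D MR-like images, with the evaluation suite that
makes "fine-grain" measurable and a seeded spine-phantom benchmark that
makes the whole pipeline runnable on one CPU.

## Why

Encoder–decoder networks segment disc *area* well but blur disc
*boundaries*: max-pooling keeps one pixel in four during feature
extraction, and the discarded neighborhood detail never comes back through
the decoder. Whole-area Dice barely registers this; Dice restricted to a
1-pixel boundary band collapses. The package implements four networks that
probe this failure mode and its fixes:

- **unet** — conventional U-net (baseline),
- **dilated_unet** — multi-rate (1/2/3) dilated blocks before each
  stride-2 down-sampling convolution,
- **cascaded_unet** — a second U-net guided at its *back end* by a frozen
  first-stage U-net's probability map,
- **bsu_net** — three-path BSU-pooling (max-pool ∥ stride-2 3×3 ∥ 1×1 →
  stride-2 3×3, fused by 1×1), residual blocks with identity shortcuts
  (H(x) = S(x) + x), and the same back-end cascade guidance.

Evaluation: Dice 2|A∩B|/(|A|+|B|) over the whole region and over 1- and
2-pixel boundary bands (mask minus its 8-connected erosion), plus the
modified Hausdorff distance max(d(A,B), d(B,A)) of directed mean
nearest-neighbour distances between boundary pixel sets, in millimetres.
Paired two-sided t-tests with ns / * / ** / *** tiers at p = 0.05 / 0.01 /
0.001 compare variants case by case.

The CNN layers run on NumPy with explicit reverse-mode gradients (verified
against finite differences), so training is dependency-light, seeded, and
bit-reproducible.

## Worked example

Reference architecture summary (exact layer and parameter totals):

```
$ bsunet summarize --variant bsu_net
{
  "variant": "bsu_net",
  "n_conv_3x3": 35,
  "n_conv_1x1": 44,
  "n_conv_total": 79,
  "n_trainable_params": 53740674
}
```

BSU-net packs 79 convolutional layers into ~53.7 M parameters — about 14 %
fewer than the conventional U-net's 62,803,650 across its 38 layers —
because 44 of its layers are cheap 1×1 convolutions.

Desk-scale benchmark (Python API): 20 phantom patients / 25 slices at
64×64, patient-exclusive 5-fold split, 1/8-width networks, 50 epochs,
two-stage cascade training included:

```python
from bsunet.benchmark import run_small_benchmark, summarize_benchmark
print(summarize_benchmark(run_small_benchmark(seed=1)))
```

```
{'unet':          {'dsc_whole': 0.818, 'dsc_boundary_1px': 0.520},
 'dilated_unet':  {'dsc_whole': 0.808, 'dsc_boundary_1px': 0.522},
 'cascaded_unet': {'dsc_whole': 0.844, 'dsc_boundary_1px': 0.595},
 'bsu_net':       {'dsc_whole': 0.819, 'dsc_boundary_1px': 0.531}}
```

(~2 min on one CPU core; values rounded to 3 digits.) Whole-area Dice is
high for every variant, while the 1-px boundary Dice is markedly lower —
the motivating gap — and the guided variants improve it over the baseline.

The same workflow from the shell:

```
bsunet phantom --n-patients 20 --total-slices 25 --seed 7 --preset small --out-dir data/
bsunet train --variant bsu_net --manifest data/manifest.csv --fold 0 --seed 7 --preset small --out-dir run/
bsunet predict --checkpoint run/checkpoint.npz --image data/p000_s0_image.png --out-dir pred/
bsunet evaluate --pred pred/p000_s0_image_mask.png --label data/p000_s0_mask.png
bsunet compare --csv-a metrics_bsu.csv --csv-b metrics_unet.csv
```

Every artifact directory receives a `resolved_config.yaml` with the
parameters and seed that produced it.

## Estimator API

`DiscSegmenter` is a scikit-learn style estimator (`fit` / `predict` /
`predict_proba` / `get_params`) over image stacks of shape `(n, H, W)`:

```python
from bsunet import DiscSegmenter, SMALL_PRESET
est = DiscSegmenter(variant="bsu_net", random_state=0, **SMALL_PRESET)
est.fit(X_train, y_train)          # trains the stage-1 U-net, then BSU-net
masks = est.predict(X_test)        # thresholded at 0.5
```

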