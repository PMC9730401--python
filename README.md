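# parotidseg

Automatic segmentation of the parotid glands and parotid tumors on
multi-sequence MRI, built around a 2D attention-gated U-Net. The package is a
complete, testable pipeline: synthetic phantom generation, NIfTI input and
preprocessing, training-time augmentation, the network and its soft-Dice
training loop, patient-level cross-validation, a four-metric evaluation
suite, and an MRI-sequence ablation harness.

Parotid tumors are rare head-and-neck neoplasms with nonspecific imaging
appearance; consistent delineation of the gland and the tumor inside it on
co-registered T1-weighted (T1w), T2-weighted (T2w) and contrast-enhanced
T1-weighted (T1wC) images supports diagnosis and quantitative-imaging
workflows. The intended users are researchers building or evaluating
organ-and-lesion autosegmentation on multi-sequence MR.

## Model

The network maps a three-channel axial slice to four independent binary
probability maps:

    input  (512 x 512 x 3)  — T1w, T2w, T1wC channels
    output (512 x 512 x 4)  — left parotid, right parotid, left tumor, right tumor

The encoder has 12 convolution blocks (3x3 convolution → batch normalization
→ ReLU) over five resolution levels with 4 max-pooling stages; the decoder
mirrors the resolutions with bilinear upsampling. Every skip connection
passes through an additive attention gate whose gating signal comes from the
network *bottleneck* (the deepest feature map): skip and gate features are
projected by 1x1 convolutions, summed, rectified, projected to one channel
and squashed by a sigmoid into a mask in [0, 1] that multiplies the skip
features. Outputs use per-channel sigmoids (no softmax), so a tumor pixel and
its enclosing parotid pixel can both be foreground.

Training minimizes `1 − soft-Dice`,

    Dice_c = (2 Σ p·t + s) / (Σ p + Σ t + s),   loss = 1 − mean_c Dice_c,

with RMSprop (defaults: learning rate 1e-4, 200 epochs). Evaluation computes,
per patient and ROI in 3D with anisotropic voxel spacing:
DICE = 2|A∩B|/(|A|+|B|), JACCARD = |A∩B|/|A∪B|, the 95th-percentile Hausdorff
distance (HD95, mm) and the average Hausdorff distance (AHD, mm), aggregated
into cohort means and 95% ranges.

Because clinical parotid MR data cannot be redistributed, the
`phantoms` module generates reproducible stand-ins: anisotropic-voxel volumes
containing two mirror-symmetric ellipsoidal glands with optional embedded
tumor ellipsoids whose contrast differs per sequence.

## Worked example

```python
import numpy as np
from parotidseg import (ModelConfig, TrainConfig, generate_cohort,
                        run_cross_validation)
from parotidseg.phantoms import small_preset

cohort = generate_cohort(6, small_preset(laterality="both"), seed=1,
                         proportions={"both": 1.0})
model_cfg = ModelConfig(in_channels=3, input_size=64, depth=3, base_filters=8,
                        encoder_block_allocation=[2, 2, 2, 2], seed=0)
train_cfg = TrainConfig(learning_rate=1e-2, epochs=25, batch_size=4,
                        folds=2, seed=1)
report = run_cross_validation(cohort, model_cfg, train_cfg)
print(report.summary[["dice_mean", "hd95_mm_mean"]].round(3))
```

Output from this exact run:

```
               dice_mean  hd95_mm_mean
roi
parotid_left       0.779        11.316
parotid_right      0.814        11.074
tumor_left         0.472         9.313
tumor_right        0.427         9.449
```

Each row is one ROI; `dice_mean` is the cohort-mean volumetric overlap of the
held-out predictions with the ground truth (1.0 = perfect), and
`hd95_mm_mean` the mean 95th-percentile surface distance in millimetres.
The glands — large, high-contrast — are learned far better than the small
embedded tumors at this miniature scale, the same qualitative ordering seen
in clinical practice.

The same pipeline is scriptable from the shell:

```bash
parotidseg phantoms --n 20 --out cohort/ --seed 7 --preset small
parotidseg cv --manifest cohort/manifest.json --config config.yaml --out results/
parotidseg ablation --manifest cohort/manifest.json --out ablation/
```

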