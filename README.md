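# tumorseg

Automated brain-tumor segmentation from 2-D MRI slices, with physical
tumor-area quantification. The package is aimed at medical-image-analysis
practitioners who want a fully testable, CPU-only reference implementation of
a lightweight attention U-Net pipeline: every stage — from data synthesis to
mm² area reports — runs at desk scale with no external dataset, no GPU, and
no deep-learning framework dependency (the networks run on a small
self-contained NumPy autodiff engine in `tumorseg.nn`).

## What it implements

**Segmentation networks.** Three encoder–decoder architectures with skip
connections and a 1×1 sigmoid head producing per-pixel tumor probabilities:

* `unet` — the classic symmetric U-Net (encoder widths 64–128–256–512,
  bottleneck 1024); 31,031,745 trainable parameters at 256×256×3.
* `vgg19_unet` — a VGG19 convolutional encoder (16 conv layers, 20,024,384
  parameters) with a standard-convolution, batch-normalized decoder.
* `proposed` — the lightweight model: the VGG19 encoder (trainable, dropout
  after each block) plus a decoder built from depthwise-separable
  transposed-convolution upsampling, skip concatenation, CBAM attention
  refinement, and runs of batch-normalized depthwise+pointwise separable
  convolution units. Under the shipped defaults (decoder widths
  128/64/32/16, six separable units per stage, CBAM reduction ratio 16) it
  has 20,420,216 trainable and exactly 2,880 non-trainable parameters
  (two batch-norm moving statistics per decoder channel).

**CBAM** (convolutional block attention module) refines a feature map
`F ∈ R^{H×W×C}` in two sigmoid-gated stages:

    channel:  M_c = σ(MLP(avgpool(F)) + MLP(maxpool(F))) ∈ (0,1)^C
    spatial:  M_s = σ(conv_{k×k}([avg_c(F'); max_c(F')])) ∈ (0,1)^{H×W}
    output:   F'' = M_s ⊙ (M_c ⊙ F)

**Classical baselines.** The thresholding rule `g(x,y) = [f(x,y) ≥ T]`, the
isodata iteration `T ← (μ_fg + μ_bg)/2` to its fixed point, and Otsu's
method (argmax of between-class variance over observed gray levels,
verified against the decomposition σ²_total = σ²_within + σ²_between).

**Training protocol.** Soft-Dice loss `1 − (2Σpo + ε)/(Σp + Σo + ε)`,
Adamax (initial learning rate 0.00025), batch size 40, up to 150 epochs,
early stopping with patience 15, best state restored by validation accuracy
(or validation Dice).

**Evaluation.** Pixel accuracy, Dice similarity coefficient
`DSC = 2|P∩O|/(|P|+|O|)`, and `IoU = |P∩O|/|P∪O|`, per-slice or pixel-pooled,
with mean ± sample-SD summaries across trials.

**Area quantification.** From a binary mask and the pixel spacing
`(S_x, S_y)` (read from DICOM tag (0028,0030), a sidecar CSV, or a flag):

    N_P = Σ_i Σ_j I(i,j)      (tumor pixel count)
    P_A = S_x × S_y           (pixel area, mm²)
    Area = P_A × N_P          (tumor area, mm²)

**Synthetic phantoms.** MRI-like slices (elliptical "brain" with smoothed
texture, one rotated hyperintense elliptical lesion, additive noise) with
analytic ground-truth masks — the mask is exactly the set of pixels whose
centers fall inside the lesion ellipse — plus pixel-spacing metadata, so the
whole pipeline is verifiable against exact integer pixel counts.

## Worked example

```python
import numpy as np
from tumorseg import (PhantomSpec, generate_dataset, ModelConfig, build_proposed,
                      TrainConfig, train, predict_mask, dice_coefficient, tumor_area)

spec = PhantomSpec(image_height=32, image_width=32, tumor_probability=1.0,
                   tumor_semi_axes_range=(4.0, 9.0), tumor_contrast=0.4,
                   noise_sigma=0.03, seed=7)
data = generate_dataset(spec, 20)

cfg = ModelConfig(architecture="proposed", input_height=32, input_width=32,
                  width_multiplier=0.125, dropout_rate=0.0)
net = build_proposed(cfg, seed=2)
tc = TrainConfig(epochs=200, batch_size=40, learning_rate=0.00025,
                 early_stop_patience=200, monitor="val_dice", seed=3,
                 mixed_precision=True)
result = train(net, data, data, tc)

dsc = np.mean([dice_coefficient(predict_mask(net, s), s.mask) for s in data])
print(f"best epoch {result.best_epoch}: mean training DSC = {dsc:.4f}")
area = tumor_area(predict_mask(net, data[0]), data[0].spacing, data[0].id)
truth = tumor_area(data[0].mask, data[0].spacing, data[0].id)
print(f"{area.sample_id}: predicted area {area.tumor_area:.1f} mm^2 "
      f"(ground truth {truth.tumor_area:.1f} mm^2)")
```

prints (about three minutes on one CPU):

```
best epoch 172: mean training DSC = 0.9857
phantom_0000: predicted area 122.0 mm^2 (ground truth 120.0 mm^2)
```

A width-multiplier-0.125 model (the VGG19 trunk shrunk 8-fold per layer,
~0.5M parameters) memorizes the 20 phantoms to a mean Dice of 0.986 within
200 Adamax steps; its predicted lesion area is within two pixels of the
analytic ground truth at 1 mm isotropic spacing. For comparison, plain Otsu
thresholding on these phantoms latches onto the brain/background boundary
(DSC ≈ 0.1 against the lesion mask) — the classical baselines segment
*something*, but only the learned model segments the tumor.

Every stage is also a CLI subcommand:

```bash
tumorseg generate-phantoms --n 100 --out data/ --seed 0
tumorseg threshold --method otsu --image data/image_0000.png --out-mask otsu.png
tumorseg summary --model proposed            # layer table + parameter census
tumorseg run-all --out results/ --n 20 --size 32 --epochs 50 --seed 0
tumorseg area --masks data/ --out areas.csv
```

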