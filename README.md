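# dnatloss

Robust training of binary segmentation networks under noisy
annotations, built around an adaptive Student's-t negative
log-likelihood. The package targets polyp segmentation in colonoscopy
frames, where annotation quality is a known problem (inter-annotator
Dice for such data is commonly reported around 0.72–0.88), but nothing
in it is specific to polyps: it applies wherever a binary mask
supervises a probability map and some of the masks are wrong.

## The loss

For an image with D pixels, residuals δ = p − y between the predicted
foreground map and the annotation, per-pixel log-precisions λ
(Σ⁻¹ = diag(e^λ)) and degrees of freedom ν:

    L = −ln Γ((ν+D)/2) + ln Γ(ν/2) − ½ Σᵢ λᵢ + (D/2) ln π + (D/2) ln ν
        + ((ν+D)/2) · ln(1 + Σᵢ δᵢ² e^{λᵢ} / ν)

Three adaptive mechanisms sit on top of this kernel:

* **ν per image**, predicted by a lightweight convolutional head
  (`NuPredictor`), so the loss runs heavy-tailed (robust) on unreliable
  images and Gaussian-like on clean ones;
* **λ per pixel and per scale**, trainable maps that learn spatially
  consistent annotation error;
* **multi-scale aggregation**: the loss is evaluated on a
  (1.0, 0.5, 0.25) pyramid with weights (1.0, 0.5, 0.3) and summed.

The package also ships the surrounding apparatus: a compact U-Net (and
a ResNet-34-topology variant) on a small NumPy reverse-mode autodiff
engine, the classic robust baselines (GCE, SCE, RCE, NGCE, MAE,
fixed-ν t-loss), a seven-metric evaluation suite (Dice, IoU, FDR,
Hausdorff, ASSD, ECE, MI), a synthetic polyp generator with
controllable annotation corruption, and a training/comparison harness
with paired t-tests. Everything runs on one CPU at desk scale; no GPU,
downloads or pretrained weights are involved.

## Worked example

```python
import numpy as np
from dnatloss import (CorruptionSpec, TrainConfig, evaluate, make_dataset, train)

corr = CorruptionSpec(kind="boundary_dilate", magnitude=2, fraction_of_dataset=0.4)
noisy_train = make_dataset(40, 64, 64, seed=100, corruption=corr)
clean_test  = make_dataset(24, 64, 64, seed=999)

cfg = TrainConfig(epochs=50, batch_size=8, image_size=(64, 64),
                  val_fraction=0.0, seed=0, loss_name="dna_tloss")
result, state = train(cfg, noisy_train)
report = evaluate(state, clean_test)
print(f"dice={report.dice:.3f}  hd={report.hd_px:.2f}px  fdr={report.fdr:.3f}")
print(f"final mean nu: {result.nu_trace[-1]:.2f}")
```

Output from this exact run:

```
dice=0.953  hd=2.37px  fdr=0.056
final mean nu: 0.10
```

Forty percent of the training masks were dilated by two pixels, yet the
model evaluated against *clean* masks reaches Dice ≈ 0.95 with a mean
Hausdorff distance under 2.5 px and ~6% false discoveries: the
heavy-tailed loss absorbs the systematically over-drawn annotations
instead of fitting them (the same configuration trained with the
Gaussian limit of the loss lands around Dice 0.93 and twice the false
discovery rate). The low final ν says the loss chose strongly heavy
tails for this noisy dataset.

The same flow is available from the shell:

```sh
dnatloss generate --out data/train --n 40 --size 64 64 --seed 100 \
    --corruption-kind boundary_dilate --corruption-magnitude 2 --corruption-fraction 0.4
dnatloss generate --out data/test --n 24 --size 64 64 --seed 999
dnatloss train --data data/train --loss dna_tloss --epochs 50 --checkpoint model.npz
dnatloss evaluate --checkpoint model.npz --data data/test
dnatloss compare --train-data data/train --test-data data/test \
    --losses dna_tloss,gaussian --seeds 0,1,2,3,4
```

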