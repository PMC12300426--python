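# caafseg

Segmentation of lung-nodule-like lesions in 2-D grayscale patches with a
residual U-Net whose channel- and position-attention branches are fused
**adaptively per sample**, trained with **boundary-aware composite
losses**. The package is aimed at researchers studying attention fusion
and boundary-sensitive training at desk scale: it ships a seeded
synthetic nodule generator, so everything here runs on a laptop CPU with
no external data.

## The model

A residual encoder–decoder (stages 32/64/128/256 channels for 64×64
inputs, ASPP bridge at 8×8) refines every stage's feature map with two
attention branches and combines them per sample:

    X_AAF = w1 · PA(X) + w2 · CA(X),      (w1, w2) = softmax(z),

where position attention PA reweights pixels by spatial affinity,
channel attention CA reweights channels by inter-channel affinity, and
the logits z come from the **adaptive attention controller** — scaled
dot-product self-attention (softmax(QKᵀ/√C)·V) over the stem feature map
pooled to 8×8, spatially averaged and passed through a small MLP. Each
input therefore chooses its own balance between "where" (PA) and "what"
(CA); the weights are returned with every prediction.

Training combines soft Dice loss with one of three boundary terms:

* **Sobel**: mean |‖∇P‖ − ‖∇G‖| (first-order edge magnitudes),
* **Laplacian**: mean |∇²P − ∇²G| (second-order response),
* **EDT-Hausdorff**: d(P→G) + d(G→P), the symmetric mean directed
  distance between foreground sets via Euclidean distance transforms,
  with a differentiable relaxation Σ P·D_G / Σ P for soft predictions.

Evaluation reports Dice, IoU, sensitivity, Miss Rate (FNR) and
specificity per case, mean ± SD across cases, and the mean fusion
weights; an ablation harness trains matched adaptive vs fixed-(0.5, 0.5)
variants and compares per-case Dice with a two-tailed paired t-test.

The tensor/optimizer substrate is a compact numpy reverse-mode autodiff
engine (`caafseg.nn`) — no deep-learning framework required.

## Worked example

```python
import numpy as np
from caafseg import generate_dataset, pipeline
from caafseg.network import NetworkConfig
from caafseg.pipeline import TrainConfig

# 60 synthetic fixtures across the five morphologies (clear, small,
# adherent, cavitary, spiculated), 32x32 patches
data = generate_dataset(60, image_size=32, seed=3)
train_set, val_set, test_set = pipeline.split_fixtures(data, seed=3)

net = NetworkConfig(input_size=32, stage_channels=(8, 16, 32), final_aspp=False)
cfg = TrainConfig(epochs=40, batch_size=8, lr=1e-3, loss_variant="hausdorff",
                  seed=3, eval_every=10, scheduler_step=1000)
record, model = pipeline.train(cfg, train_set, net, val_data=val_set)

frame, summary = pipeline.evaluate(model, test_set)
print(f"dice {summary['dice_mean']:.3f} +/- {summary['dice_std']:.3f}  "
      f"miss rate {summary['miss_rate_mean']:.3f}  "
      f"w1 {summary['w1_mean']:.2f} w2 {summary['w2_mean']:.2f}")
```

which prints (≈30 s on one CPU; a logged warning notes that the larger
ASPP dilations exceed the 8×8 bridge grid at this reduced scale):

```
dice 0.698 +/- 0.214  miss rate 0.322  w1 0.62 w2 0.38
```

Read: on the nine held-out fixtures the mean per-case Dice overlap is
69.8% and 32.2% of true lesion pixels are missed — the uniform mix
includes the sub-5-pixel morphology, which is hard at this tiny training
scale and drags both numbers; the controller leaned towards position
attention for these inputs (w1/w2 are per-sample means of the adaptive
weights). `frame` holds the per-case CSV rows (case_id, dice, iou,
sensitivity, miss_rate, specificity, w1, w2) plus a mean row.

A command-line interface wraps the same calls. With a `config.yaml`
holding the settings above,

```yaml
network: {input_size: 32, stage_channels: [8, 16, 32], final_aspp: false}
train:   {epochs: 40, batch_size: 8, lr: 1.0e-3, loss_variant: hausdorff,
          eval_every: 10, scheduler_step: 1000}
```

the same experiment runs as:

```bash
caaf-seg synth --n 60 --size 32 --seed 3 --out data/
caaf-seg train    --config config.yaml --data data/ --seed 3 --out run/
caaf-seg evaluate --checkpoint run/best.npz --data data/ --out eval/
caaf-seg predict  --checkpoint run/best.npz --data data/ --out preds/
caaf-seg ablate   --config config.yaml --data data/ --seed 3 --out ablation.json
```

`predict` writes binary masks and, when ground truth is present,
four-colour difference maps (green = true positive, blue = true
negative, red = false positive, yellow = false negative).

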