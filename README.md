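# dcclnet

Semi-supervised medical image segmentation by **deep consistent
collaborative learning**: a U-Net backbone trained from a handful of
labeled images plus a large unlabeled pool, using three cooperating
sources of unsupervised signal —

* **feature-perturbation consistency**: three auxiliary decoders decode
  perturbed copies of the shared encoder's bottleneck (multiplicative
  uniform noise, attention-guided feature dropout, channel dropout) and
  are pulled towards the main decoder by MSE;
* **input-perturbation consistency**: a mean-teacher U-Net — an
  exponential moving average of the student, `θ_t = λθ_{t−1} + (1−λ)θ_s`
  — predicts on noised inputs and guides the student by MSE;
* **CNN–transformer co-training**: a compact Swin-style transformer and
  the U-Net supervise each other on unlabeled images through detached
  argmax pseudo-labels, symmetrically with soft Dice.

With supervised CE+Dice terms on the labeled batch, the total objective
is

```
L = L_sup^U + L_sup^SU + λ1·(L_aux + L_tea) + λ2·L_cot
λ1(t) = 0.01·exp(−5(1 − t/tmax)²),   λ2(t) = 15·λ1(t)
```

where the ramp step `t` advances every 150 iterations — the model
focuses on labeled data early and phases unlabeled terms in.

The package is aimed at researchers studying consistency regularisation
and co-training for segmentation under scarce labels. It ships a seeded
synthetic phantom generator (multi-class cardiac-like structures with
contrast, bias field and noise), readers for real 2-D data (NIfTI slices
or PNG pairs), evaluation metrics (DSC, HD95, ASD) verified against
brute-force oracles, and a CLI. It runs entirely on numpy via a built-in
gradient-checked reverse-mode autodiff engine — no GPU framework
required. See `docs/methods.md` for the full model description and
design choices.

## Worked example

Train the full framework on a synthetic fixture with 10 % labeled
images (4 labeled, 38 unlabeled), then inspect the run:

```python
from dcclnet import DCCLNet, PhantomSpec, RunConfig, make_split

spec = PhantomSpec(image_size=32, n_images=60, labeled_fraction=0.1, seed=0)
data = make_split(spec)

config = RunConfig(n_classes=4, batch_labeled=4, batch_unlabeled=4,
                   total_iters=500, eval_every=50, unet_depth=3,
                   unet_base_channels=8, swin_embed=24, ramp_every=2, seed=0)
results = DCCLNet(data, config).fit()
print(results.summary())
```

```
Deep Consistent Collaborative Learning — training summary
============================================================
components:        unet+aux+teacher+vit
iterations:        500
labeled / unlabeled images: 4 / 38
best iteration:    500
best val DSC:      0.8372

test metrics (foreground classes):
   class      DSC     HD95      ASD
       1   0.8750    1.274    0.475
       2   0.8629    1.054    0.277
       3   0.9117    1.093    0.395
    mean   0.8832    1.140    0.383
```

The summary reports the checkpoint selected by best validation mean
foreground Dice (class 0/background excluded), then per-structure test
metrics from that checkpoint: Dice overlap in [0, 1] (higher is better)
and the two boundary distances in pixels (lower is better) — HD95 is the
95th-percentile surface distance, robust to outliers; ASD the average
symmetric surface distance. Ablations toggle each mechanism:
`RunConfig(components=Components(aux=False, teacher=False, vit=False))`
is the supervised-only baseline; on this same fixture it reaches a lower
validation Dice (0.8151), illustrating the semi-supervised benefit the
acceptance suite tests across seeds.

The same workflow from the shell:

```bash
dcclnet generate-data --spec spec.yaml --out fixtures.h5
dcclnet train --config run.yaml --data fixtures.h5 --out rundir/
dcclnet ablate --grid aux,teacher,vit --data fixtures.h5 --out ablation/
dcclnet evaluate --checkpoint rundir/best.ckpt --data fixtures.h5 \
    --split test --report report.json
```

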