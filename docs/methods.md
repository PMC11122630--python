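# Methods

## The problem and the model

Pixel-accurate annotation of medical images is expensive, so a practical
training set usually contains a handful of labeled images and many
unlabeled ones. `dcclnet` implements a semi-supervised segmentation
framework that extracts training signal from the unlabeled pool through
three complementary mechanisms wrapped around a U-Net backbone:

1. **Feature-perturbation consistency (auxiliary decoders).** Unlabeled
   images pass once through the shared U-Net encoder. Three perturbed
   copies of the bottleneck feature map `h` are decoded by three
   auxiliary decoders whose architecture matches the main decoder but
   whose parameters are independent. The mean MSE between the main
   decoder's softmax map and each auxiliary map,

       L_aux = (1/3) Σ_{i=1..3} MSE(f_U(x_u), f_Ai(x_u)),

   pushes the backbone towards predictions that are stable under feature
   disturbance. Gradients flow into both the main and auxiliary branches.
   The three perturbations, fixed one per decoder, are:
   * *feature noise* — `h' = h ∘ N + h`, `N ~ U(-3, 3)` i.i.d., so the
     injected noise is proportional to each activation;
   * *feature dropout* — the channel-mean of `h`, max-normalised to
     [0, 1], is thresholded at `γ ~ U(0.6, 0.9)`; spatial positions at or
     above `γ` (the most active regions, 10–40 % of a uniformly active
     map) are zeroed across all channels;
   * *dropout* — channel-wise spatial dropout, p = 0.5, inverted scaling.

2. **Input-perturbation consistency (mean teacher).** A teacher U-Net
   holds the exponential moving average of the student's parameters,
   `θ_t = λ θ_{t−1} + (1 − λ) θ_s`, updated once per iteration after the
   optimizer step, with λ = 0.99. The teacher sees a noised copy of the
   unlabeled batch (clipped Gaussian, σ = 0.1, clip 0.2) and the student
   is pulled towards the teacher's gradient-detached prediction:
   `L_tea = MSE(f_U(x_u), f_T(x_u + ε))`. The teacher never appears in
   any optimizer parameter group (asserted at construction).

3. **CNN–transformer co-training.** A compact Swin-style transformer
   segmenter is trained alongside the U-Net. On unlabeled data each
   network is supervised by the *other's* hard argmax pseudo-label
   (gradient-detached), symmetrically with soft Dice:

       L_cot = Dice(f_U(x_u), ŷ_SU(x_u)) + Dice(f_SU(x_u), ŷ_U(x_u)).

   The two architectures observe the data through different inductive
   biases (locality vs. long-range attention), so their mistakes are
   partly decorrelated and each provides a useful target for the other.

Labeled images reach only the two backbones, where each pays the usual
supervised cost `0.5·(CE + Dice)` against ground truth. The total
objective is

    L = L_sup^U + L_sup^SU + λ1 (L_aux + L_tea) + λ2 L_cot.

**A note on the total-loss formula.** The source description of this
framework prints the co-training loss a second time where the total loss
belongs; the total used here is reconstructed from the accompanying
prose (λ1 weights the consistency losses, λ2 the collaborative-training
loss) and is asserted per-iteration by the loss-accounting invariant in
the test suite.

**A note on feature dropout.** The source formula masks the *attention
map* (`h' = F_drop ∘ ĥ`) even though the auxiliary decoder consumes
features. We mask the feature map (`h' = F_drop ∘ h`), matching the
cross-consistency-training design this mechanism derives from; the
literal reading remains available via
`PerturbationConfig(mask_target="attention")`. "Channel-wise summation
and normalisation" is implemented as channel *mean* divided by the
spatial maximum — sum and mean give identical masks after
max-normalisation for nonnegative (post-ReLU) activations.

## Schedules

* **Ramp-up weights**: `λ1(t) = 0.01 · exp(−5 (1 − t/tmax)²)`,
  `λ2(t) = u · λ1(t)` with u = 15. The ramp step `t = ⌊iter/150⌋`
  advances every 150 iterations up to `tmax = total_iters / 150` (200 at
  the full 30 000-iteration scale); within a window the weights are
  constant, and λ1 saturates at exactly 0.01 at `t = tmax`. Early
  training therefore concentrates on the labeled images; unlabeled terms
  phase in as the supervised signal stabilises.
* **Learning rate**: SGD (momentum 0.9, weight decay 1e−4 — conventional
  companions, exposed in config) with the poly policy
  `lr = 0.01 · (1 − iter/total_iters)^0.9`. The exponent 0.9 is the
  conventional segmentation choice; only the policy name and base rate
  are prescribed upstream.
* **EMA decay** λ = 0.99 (standard mean-teacher value; no value is
  prescribed upstream). Batch-norm running statistics are EMA-tracked
  exactly like weights. A warm-up variant
  `min(0.99, 1 − 1/(count+1))` exists but is off by default. The teacher
  is initialised as a parameter copy of the student.

## Architectures

* **U-Net**: depth 4, base 16 channels by default (the smallest commonly
  working configuration; no hyperparameters are prescribed upstream),
  double conv + batch norm + ReLU per level, 2×2 max-pool down, bilinear
  ×2 up with skip concatenation, 1×1 class head. The encoder/decoder
  split is explicit so the main, auxiliary and teacher decoders can
  share or mirror one encoder.
* **Swin-style segmenter**: patch embedding 4, embed dim 48, 2 heads,
  window 4, two encoder stages (patch merging between) and a mirrored
  decoder (patch expansion, one skip), 2 blocks per stage with shifted
  windows in alternate blocks (cyclic shift + cross-region masking),
  learned relative-position bias per window, final ×4 patch expansion
  and linear head. When a window already spans the whole grid the shift
  is disabled, as is standard — shifting there would mask all
  cross-token attention. This is a compact stand-in for a full-size
  pretrained Swin-UNet: the framework's mechanics, not ImageNet
  initialisation, are what is under study, and larger configurations
  remain reachable through the config.

## Compute backend

No GPU tensor framework is part of the dependency set; the package
carries its own small reverse-mode autodiff engine on numpy
(`dcclnet.autodiff`) with the structured operations the two networks
need (stride-1 convolution via im2col, 2×2 max-pooling, separable
bilinear upsampling, windowed attention primitives, softmax, cyclic
roll). Every operation and both networks are verified end-to-end against
central finite differences in the test suite. Training runs in float32;
the engine follows the input dtype, so the numerical tests run the same
code paths in float64.

## Synthetic phantoms

The generator emulates the statistical structure of a short-axis cardiac
segmentation task: a bright elliptical cavity (class 3) inside a darker
annular shell (class 2) with an adjacent crescent-shaped chamber
(class 1) over background — three foreground structures whose pose, size
and orientation vary per image. Class mean intensities are evenly spaced
(gap 0.75/(C−1), small per-image jitter capped so the pre-noise
separation always stays ≥ 2·noise_sigma, enforced at spec validation), a
smooth multiplicative sinusoidal bias field emulates coil shading, and
clipped additive Gaussian noise (σ = 0.05 by default) is applied last.
Labels are rasterised exactly: a pixel belongs to the innermost shape
covering its centre. Datasets split 70/10/20 % into train/val/test;
`labeled_fraction` applies only inside the train pool.

What the phantoms do *not* model: 3-D anatomy and through-plane
correlation between slices, MRI acquisition physics (k-space artifacts,
partial volume), pathological shape variation, and inter-observer label
noise. Passing the fixture experiments therefore demonstrates that the
training mechanics behave as designed (consistency terms help when
labels are scarce), not that any particular clinical accuracy would be
reached on real data.

## Study sizes and numerical choices

* The *directional experiment* (does the full framework beat the
  supervised-only baseline when labels are scarce?) runs on 32×32
  phantoms, 60 images at 10 % labeled (4 labeled / 38 unlabeled / 6 val
  / 12 test), batch 4+4, depth-3/base-8 U-Net, embed-24 transformer, 500
  iterations with the ramp step advancing every 2 iterations
  (tmax = 250), seeds {0, 1, 2}. These sizes are the package's chosen
  desk-scale study; the full-scale defaults (224×224, depth-4/base-16,
  batch 8+8, 30 000 iterations, ramp every 150) remain the config
  defaults. The claim tested is only the *sign* of the improvement
  (best-val mean foreground DSC of full ≥ supervised-only in ≥ 2 of 3
  seeds), never the magnitudes reported for real cardiac/prostate data.
* The *ablation lattice* (all 8 on/off combinations of auxiliary
  decoders, teacher, transformer) runs 200 iterations each on 16×16
  phantoms with minimal networks — a smoke check that every combination
  trains with finite losses and exactly-zero disabled terms.
* Soft Dice smoothing ε = 1e−5 (config field); Dice *loss* includes the
  background class for stability on scarce-foreground images, while the
  evaluation metrics exclude it.
* Consistency MSEs act on softmax probabilities, not logits (logit-space
  MSE is scale-unbounded).
* Pseudo-label and argmax ties break towards the lowest class index.
* Model selection: the checkpoint with the best validation mean
  foreground DSC of the backbone U-Net (not the teacher, not the
  transformer); final test metrics come from that checkpoint.
* Evaluation metrics: DSC from exact confusion counts; HD95 as the 95th
  percentile (linear interpolation) of the pooled directed
  surface-to-surface nearest-neighbour distances; ASD as the
  symmetric-sum average. Surface = foreground pixel with a background
  4-neighbour, image border counting as background. Both masks empty ⇒
  perfect score; exactly one empty ⇒ DSC 0 and distances set to the
  image diagonal (a bounded, monotone-safe penalty instead of infinity).
  The printed formula for the 95 % Hausdorff distance in the source
  material is garbled; the implementation follows the standard
  convention used by the cited evaluation tooling. Pixel spacing
  defaults to 1.0 and a spacing vector scales distances anisotropically
  for real volumes.
* One master seed drives named, independent RNG sub-streams (data order,
  augmentation, each initialiser, each perturbation), so toggling one
  component never shifts another component's random sequence — ablations
  stay comparable draw-for-draw.
* Augmentation is axis-aligned (rotations by multiples of 90° plus
  flips) applied identically to image and label, so label maps are never
  interpolated; free-angle rotation is deliberately avoided.

## Known limitations

* CPU-only and modest by design: full-scale 224×224 / 30 000-iteration
  runs are possible but slow on this backend; the package's purpose is
  the faithful, tested mechanics of the training framework.
* Labeled images do not flow through the auxiliary decoders or the
  teacher (by the framework's routing); no uncertainty weighting or
  pseudo-label filtering is applied — those belong to other methods.
* 2-D only; volumes are handled as independent slices, and the
  volume-grouped 3-D surface evaluation mode is off by default.
* No pretrained transformer weights; the co-training branch is a compact
  Swin-style network trained from scratch.
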