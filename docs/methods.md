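# Methods

This note documents the model, the numerical and design choices, and what
the synthetic benchmark does and does not demonstrate.

## Model and training procedure

The instance scorer is a binary classifier over tiles trained with only
slide-level supervision.  One training epoch consists of:

1. **Teacher scoring.** The teacher network scores every tile of every
   training bag in evaluation mode (no augmentation).
2. **Dynamic pseudo-labeling.** Within each bag, the `M = max(1,
   round(p·n))` top-scoring tiles (positive bags) or bottom-scoring tiles
   (negative bags) receive the bag label; ties break toward the lowest
   tile index so selection is deterministic.  The proportion `p` is tied
   to the expression cutoff: 0.25 (upper quartile), 0.35 (upper tertile),
   0.45 (median) — looser cutoffs imply more label-consistent tiles per
   slide.
3. **Student update.** Shuffled mini-batches mix labeled and unlabeled
   tiles.  Each tile is augmented once per step; teacher and student see
   the *same* transformed input (an option for independent transforms,
   classic mean-teacher noise, exists but is off by default).  The loss is
   the inverse-class-frequency-weighted cross-entropy on labeled tiles
   plus λ times the squared probability gap on unlabeled tiles, summed and
   divided by the batch size.  Probabilities are clipped at 1e-7 before
   logarithms.
4. **EMA teacher update** after every optimizer step, followed by the
   cosine learning-rate step.

Per-epoch logs record the learning rate, both loss components, and the
pseudo-label churn (mean fraction of each bag's labeled set replaced since
the previous epoch; defined as 1.0 at the first epoch, when every label is
new).

### Defaults (and why)

| parameter | default | rationale |
|---|---|---|
| tile side | 256 px (128 μm at 0.5 μm/px) | standard 20× tiling |
| mask thresholds | HSV saturation, hysteresis 0.05/0.15, 32× thumbnail | stained tissue is saturated against white background regardless of stain hue |
| min tissue fraction | 0.05 | keeps partly overlapping boundary tiles, drops slivers |
| λ (consistency) | 100 | consistency cost weight on unlabeled tiles |
| α (EMA decay) | 0.99 per optimizer step | temporal-ensemble horizon of ~100 steps |
| SGD | lr 1e-2 → 1e-4, cosine, 2 warm restarts, momentum 0.9, batch 512 (scalable down) | momentum is the standard companion of SGD for conv nets |
| epochs | 30 | two full cosine cycles |
| MLP head | (d+11)→256→64→2, ReLU, SGD lr 2e-4, ≤500 epochs | small enough to converge at desk scale |

### Desk-scale adaptations

Three choices make the procedure stable and fast at desk scale (tens of
slides, hundreds of tiles, tens of optimizer steps per epoch); each
reduces to the published-scale behaviour when the step count grows:

- **Scale-aware EMA horizon.** The effective decay is
  `min(α, 1 − 1/steps_per_epoch)`, capping the teacher's averaging window
  at one epoch, with the usual warm-up `min(α, 1 − 1/(t+1))` over the
  first steps.  With thousands of steps per epoch this is exactly
  α = 0.99; with tens of steps a fixed 0.99 would leave the teacher at its
  random initialization for the whole run, and — because the consistency
  cost pulls the student toward the teacher — anchor every probability
  near 0.5.
- **Consistency ramp-up.** λ follows the sigmoid ramp `exp(−5(1−t)²)`
  over the first 40% of epochs (`consistency_rampup=0.4`; final value
  still λ).  Without it the consistency cost dominates before the
  pseudo-labels carry any signal and can collapse both models onto a
  constant output.
- **Supervised warm-up epoch.** During the first epoch every tile is
  labeled with its bag label (proportion 1.0).  Background morphology
  occurs in both classes, so its gradients cancel, while witness
  morphology occurs only in positive bags — this breaks the selection
  symmetry in the correct direction.  Without it, max-min selection is
  self-reinforcing in whichever direction the random initialization
  happens to rank tiles, occasionally converging to a perfectly inverted
  scorer.  (A pretrained encoder initialization serves the same purpose
  where available.)

The encoder is a 3-block convolutional network (3→16→32→32 channels,
global average pooling, d = 32) over tiles block-mean-downsampled to
32 × 32 — deliberately small so the full cycle trains in about two
minutes on one CPU.  The architecture is configurable (`encoder_widths`,
`encoder_side`); the aggregation layer is dimension-agnostic, so the
523-dimensional embedding of a d = 512 encoder is exercised directly.

## Slide aggregation

The fusion block is the minimal structure implementing
`H = LN(MSA(·))`: a learnable class token prepended to the tile-feature
sequence, one multi-head self-attention layer (2 heads at d = 32, 8 heads
at d ≥ 64), layer normalization, no residual connection and no positional
encoding — hence exact permutation invariance in tile order.  The token,
attention weights and MLP are trained jointly with softmax cross-entropy.

The 11 summary statistics are computed from the teacher's tile
probabilities after removing values outside [0.2, 0.8] (a trimmed
estimator of central tendency): the fraction above 0.5, an 8-bin histogram
over the trimmed support normalized to sum 1, the median and the mean.
The 8-bin width is forced by the embedding size: d + 11 = 523 at d = 512
with three scalar statistics.  If every probability is extreme the
untrimmed list is used with histogram support [0, 1].

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counted one
half.  The operating threshold maximizes Youden's J = sensitivity +
specificity − 1 over the observed scores (prediction rule: score ≥ t;
smallest maximizer returned on ties).  Confidence intervals are
percentile bootstrap over slide-level case resamples (default 2000;
resamples missing a class are redrawn).  MCC returns 0 when any
denominator factor vanishes.  The matched-patch correlation selects the
⌈fraction·N⌉ highest-predicted patches plus, by default, an equal-sized
lowest-predicted set, so Pearson r stays defined under near-constant
references; a pure top-fraction mode is available.

## Synthetic data: what it emulates, and what it does not

Each synthetic slide is a white canvas with an irregular blob-shaped
tissue region in a pink/purple base texture, sparse light nuclei
throughout, and — on positive slides — a spatially contiguous region of
tiles carrying a dense dark-nucleus motif covering
`round(witness_rate × n_tissue_tiles)` tiles.  Defaults: 1536 px slides
(6 × 6 tile grid), ~70% tissue coverage, witness rates uniform in
[0.2, 0.5], 0.5 μm/px.  Expression values are drawn strictly above a
fixed cutoff for positive slides (shifted lognormal) and within
[0, cutoff] (scaled Beta(2,2)) otherwise, so percentile dichotomization
recovers the planted labels.  Witness density is calibrated so witness
and background tiles separate by mean darkness (AUC ≥ 0.95): the learning
problem is solvable, but not by a slide-level shortcut, since background
texture is drawn identically for both classes.

The generator satisfies the MIL bag rule by construction and exposes
per-tile ground truth, which real data never does.  It does **not**
emulate stain variation across laboratories, pen marks and artifacts,
out-of-focus regions, the continuous (rather than binary) nature of
expression within a slide, or any mismatch between bulk RNA measurement
and the imaged section.  Passing the synthetic benchmark therefore
demonstrates that the training dynamics recover planted instance
structure from bag labels at desk scale — not clinical-grade performance
on real cohorts.

## Benchmark problem sizes

The shipped benchmark uses 60 slides (50% positive, one slide per
patient), the d = 32 encoder, 10 epochs at batch 64, and a 36/9/15
patient split; the ablation comparison (full method vs fully supervised
slide-label painting with mean-pooled probabilities, i.e. λ = 0 and
proportion 1.0) uses three seeds of 24 slides at 1024 px for 6 epochs;
the bootstrap-coverage simulation uses binormal scores (n = 200, true
AUC Φ(1/√2) ≈ 0.760), 200 replicates and 500 resamples.  All runs are
deterministic under a fixed seed on a single CPU thread.

## Known limitations

- No pyramidal/SVS reader: slides are plain rasters with a caller-supplied
  microns-per-pixel; real WSIs must be exported to PNG/TIFF at 20× first.
- No stain normalization or artifact detection (out of scope).
- The ResNet-scale encoder of the published configuration is not included;
  the encoder family is the configurable small conv net above, and d = 512
  behaviour is exercised only through the aggregation layer.
- `cosine_lr` normalizes phase by (cycle_steps − 1) so both stated
  endpoints (start 1e-2, trough 1e-4) are met exactly; for very short
  cycles this slightly steepens the schedule.
- Bootstrap CIs are plain percentile intervals; no bias correction or
  acceleration is applied.
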