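# milts

Teacher–student multiple-instance learning for predicting a slide-level
gene-expression label (e.g. dichotomized *PDL1* FPKM-UQ) from hematoxylin
& eosin tile images, with per-tile probability heatmaps and attention-based
slide embeddings for patient-level classification.

## The problem

Bulk mRNA quantification gives one continuous expression value per sample,
while a whole-slide image contains tens of thousands of 256 × 256 px tiles
(128 μm × 128 μm at 20×), only some of which carry the morphology
associated with high expression.  Dichotomizing expression at a per-cancer
percentile cutoff (median, upper tertile, or upper quartile) yields a
binary *slide* label `Y_k`, but no tile labels — the classic
multiple-instance learning (MIL) setting:

```
Y_k = 0  if Σ_i y_{i,k} = 0,   else 1
```

where `y_{i,k}` is the (unobserved) label of tile `x_{i,k}` in bag `X_k`.

## The method

**Class-targeted representative selection.** An instance scorer `f_θ` maps
each tile to a typicality in [0, 1].  Each epoch, within each bag, the
`M = round(p · n)` tiles with *maximum* score (positive bags) or *minimum*
score (negative bags) are pseudo-labeled with the bag label; `p` is 0.25 /
0.35 / 0.45 for the quartile / tertile / median cutoff.

**Teacher–student consistency.** A teacher `f_θ'` — the exponential moving
average of the student's parameters after every optimizer step
(θ' ← α θ' + (1 − α) θ, α = 0.99) — does the scoring and selection.  The
student minimizes

```
L = −Σ_labeled [ ω₊ y log f_θ(x) + ω₋ (1 − y) log(1 − f_θ(x)) ]
    + λ Σ_unlabeled ‖ f_θ'(T(x)) − f_θ(T(x)) ‖²
```

with class weights ω from inverse slide-label frequency, consistency
weight λ = 100 on the ambiguous (unlabeled) tiles, and a shared stochastic
transform `T` (rotation, flips, crop, color jitter).  Optimization is SGD
(lr 1e-2 → 1e-4, cosine annealing with two warm restarts over 30 epochs).

**Slide aggregation.** Tile features `e = [e₁ … e_m]` are fused through a
learnable class token plus one multi-head self-attention block,
`H_k = LN(MSA(e))`; the class-token row is concatenated with an 11-value
trimmed statistical summary of the tile probabilities (positive fraction,
8-bin histogram, median, mean, computed after removing tiles with
typicality < 0.2 or > 0.8) into the slide embedding — ℝ^523 for a d = 512
encoder — which a two-hidden-layer MLP classifies (SGD, lr 2e-4).

The neural-network core (convolutional scorer, attention fusion, manual
backpropagation, momentum SGD) is a compact, dependency-light NumPy
implementation, gradient-checked against finite differences in the test
suite, and fully deterministic under a fixed seed on one CPU thread.

Because real cohorts (TCGA/CPTAC) are not redistributable, the package
ships a synthetic slide generator that plants a contiguous region of
"witness" tiles (dense dark nuclei) in positive slides at a controlled
rate and records per-tile ground truth, so the entire train/evaluate
cycle — including instance-level recovery of the witness tiles — runs at
desk scale in minutes.

## Worked example

```python
from milts import RunConfig, run_experiment

cfg = RunConfig(seed=5, n_patients=12, image_size=1024, epochs=3,
                batch_size=32, mlp_epochs=60, bootstrap_resamples=300)
res = run_experiment(cfg)
print(res.metrics.to_json())
print("instance_auc:", res.instance_auc)
```

prints

```
{
  "accuracy": 1.0,
  "auc": 1.0,
  "ci_high": 1.0,
  "ci_low": 1.0,
  "f1": 1.0,
  "mcc": 1.0,
  "n": 2,
  "sensitivity": 1.0,
  "specificity": 1.0,
  "threshold": 0.512916088104248
}
instance_auc: 1.0
```

The pipeline generated 12 synthetic slides, tiled them after hysteresis
tissue masking, split patients 60/15/25, trained the teacher–student
scorer for 3 epochs, fitted the attention + MLP slide classifier, and
evaluated the 2 held-out test slides: `auc`/`accuracy`/... are slide-level
metrics at the Youden-J threshold with a percentile bootstrap CI, and
`instance_auc` is the AUC of the teacher's tile typicality against the
generator's planted witness flags on the test slides (here both perfect —
a 12-slide toy run; the shipped benchmark uses 60 slides).

The same flow is scriptable from the shell:

```bash
milts synth --patients 20 --out data/ --seed 7
milts label --manifest data/manifest.csv --threshold tertile --out labeled.csv
milts run --out run_out/ --seed 7          # end-to-end with defaults
milts predict --run run_out/ --slide data/slides/SYN-P000-S0.png --heatmap hm.png
```

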