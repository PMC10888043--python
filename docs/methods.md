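# Methods

`petctsurv` implements a multi-modal deep survival pipeline for co-registered
PET/CT volumes with structured clinical covariates: self-supervised
(masked-autoencoder) pretraining of one vision-transformer encoder per
modality, cross-attention PET/CT feature fusion, Q-Former image–text fusion,
and a time-indexed partial-likelihood loss with a sigmoid relative-risk link.
This note records the model, the synthetic study conditions, and the
numerical and design choices, in enough detail to reproduce or challenge
them.

## Survival model and losses

The hazard is modelled as `lambda(t, x) = lambda0(t) * g(x, t)` with a neural
relative-risk term `g(x, t) = sigmoid(N(y, t))`, where `y` is the fused
image–text representation of a subject and `N` is the risk head. The training
objective is the negative log partial likelihood over events,

    l = -(1/N_events) * sum_{i: E_i = 1} [ log sigma(N(y_i, T_i))
          - log sum_{j: T_j >= T_i} sigma(N(y_j, T_i)) ],

i.e. at each event time the subject that failed competes against its risk set,
everyone scored *at that time*. The baseline hazard cancels between numerator
and denominator, exactly as in Cox regression, and consequently never appears
in the code. Two properties distinguish the sigmoid link from the classical
exponential link: scores enter bounded in (0, 1), and the loss is not
invariant to score translation. With the exponential link substituted and
time-invariant scores, the loss reduces exactly to the Breslow partial
likelihood; the test suite verifies this against an independent Cox
implementation to 1e-10.

Ties use the Breslow convention (tied events share the full risk set). The
per-event normalization makes the loss scale-free in cohort size. Numerical
stability: `log sigma(x) = -softplus(-x)`, and risk-set log-sums use
max-shifted exponentials restricted to the risk-set mask, so no infinities
enter the graph.

Two auxiliary losses are available and combinable by configuration flags:
the classical Cox partial likelihood (time-invariant scores,
log-sum-exp-stabilized) and a focal loss on `sigma(N(y_i, T_i))` against the
subject's event indicator (gamma = 2 by default; gamma = 0 recovers binary
cross-entropy). The default configuration is sigmoid partial likelihood +
focal, the strongest arm of the loss ablation. The focal input is clamped to
`[1e-12, 1 - 1e-12]` because the sigmoid saturates exactly in float64 beyond
|x| ≈ 37. What the focal loss supervises is a genuine modelling choice (it is
a calibration term, and censored subjects enter as non-events, which is
biased under heavy censoring); it is kept because the loss ablation favors
it, with weight 1 by default.

## Differentiation and optimization

No deep-learning framework is used: all neural components run on an
in-package reverse-mode automatic-differentiation engine over float64 numpy
arrays, with AdamW (decoupled weight decay, optional linear warmup)
implemented alongside. Gradient correctness is pinned by central
finite-difference checks at 1e-5 relative tolerance, which float64 makes
meaningful. This keeps the dependency footprint to the scientific Python
stack and makes every gradient auditable.

## Preprocessing

Intensity preprocessing is two-sided winsorization — values below the 0.001
quantile and above the 0.90 quantile are clipped to those cut points — then
an affine map to [0, 1]. The cut points use `lower`/`higher` order-statistic
conventions rather than interpolated quantiles; this makes the operation
exactly idempotent (interpolated quantiles shift after clipping adds mass at
the boundary). Volumes are reduced to 2-D model inputs by taking the axial
slice with the largest in-mask tumor area (central slice without a mask),
center-crop/padding to square, and bilinear resampling to the configured
side (224 at full scale, 64 at desk scale). Bilinear interpolation cannot
overshoot, and outputs are clamped to [0, 1].

## Architecture

*Encoders.* One ViT per modality, architecturally identical, never sharing
weights. MAE pretraining masks a uniformly random 75% of patches per step
(one plan per batch, fresh every step), encodes only visible patches with
positional embeddings indexed by original grid positions, and reconstructs
per-patch-standardized pixels with a light decoder; the loss is MSE over
masked positions only. Encoders are frozen after pretraining.

*PET/CT fusion.* Single-map cross-attention: Q and K are linear projections
of the CT tokens, V of the PET tokens (PET carries metabolic plus anatomical
signal; CT gates where to look), output `softmax(QK^T/sqrt(d))V` followed by
a residual feed-forward block. Swapped roles, pooled concat+FC, and
single-modality self-attention (`fuse(x, x)`) are selectable ablation modes.

*Image–text fusion.* A Q-Former: a small set of learnable query tokens that
per block (1) self-attend jointly with the clinical-text tokens, (2)
cross-attend into the fused image tokens, (3) pass a feed-forward block.
Clinical fields (age decade, sex, T, N, M, overall stage) are embedded via
lookup tables, one token per field — never ordinal numeric codes. The
Q-Former trains end-to-end under the survival loss only; the BLIP-2
contrastive/matching pretraining stages are deliberately omitted.

*Risk head.* The head consumes the mean-pooled query tokens concatenated
with a low-level *patch-evidence* vector (below) and a sinusoidal embedding
of `t / time_scale` (`time_scale` = 4000 days ≈ maximum follow-up), and
returns the pre-link score `N(y, t)`; the sigmoid lives inside the loss. At
desk scale the head is linear; the full-scale preset uses an MLP.

### Small-cohort design choices (and why)

Desk-scale training (160 training subjects, 50 fine-tuning epochs) is a
different optimization regime from the full-scale recipe, and three failure
modes dominate it. Each motivated a documented design choice:

1. **Patch-evidence stream.** A tumor occupies a handful of the 64 image
   tokens. Mean pooling dilutes it below between-subject background
   variability, and statistics like "area above an uptake threshold" need a
   per-patch nonlinearity *before* pooling — which attention-mixed features
   do not provide while attention is still diffuse. The evidence stream is a
   **fixed bank of soft intensity-threshold features** on raw pixel patches
   (uniform spatial filters with spread thresholds and slopes), mean-pooled
   over patches. Pooled, each channel starts as a soft "area above threshold
   theta" — the classic thresholded-volume biomarker (metabolic tumor volume
   in PET). Like a radiomics panel, the bank is frozen: the head learns how
   to weight it, not what it measures.
2. **Frozen feature standardization.** Pooled features have heterogeneous
   scales, which interacts badly with uniform weight decay (informative
   small-scale channels need large weights, which the decay suppresses).
   Per-dimension mean/sd are computed once from the initial model's
   training-set features and frozen.
3. **Augmentation.** Fine-tuning applies per-sample dihedral (flip/rot90)
   augmentation to the encoder stream and fresh random translations (±8 px)
   to the evidence stream each step; prediction averages over the eight
   dihedral variants. Without this, per-patch gates memorize
   subject-specific background patterns within a few hundred steps.

With these, held-out OS concordance at desk scale is stable across cohort
seeds (median ≈ 0.72, range ≈ 0.64–0.81 over ten seeds) where the naive
mean-pool readout ranged 0.49–0.78.

Fine-tuning uses batch size 16 (≈ 500 optimization steps in 50 epochs),
risk sets formed within batch, AdamW at lr 1e-2 with 5-epoch linear warmup
and weight decay 5e-2. The full-scale preset mirrors the published recipe
(batch 128/256, 1000/300 epochs, lr 1e-4, warmup 10, AdamW betas
(0.9, 0.95)/(0.9, 0.999), weight decay 1e-2/5e-2).

## Evaluation

The scalar ranking score of subject `j` is `sigma(N(y_j, t_med))` at the
evaluation-set median follow-up time (how a time-indexed score becomes one
ranking is underdetermined; this is the implemented convention — the learned
scores are nearly time-flat at desk scale, so grid-averaging changes little).
Per endpoint the evaluator reports Harrell's C with a percentile-bootstrap
confidence interval (subject-level resampling, B = 1000, resamples with an
undefined statistic skipped, >10% skips an error), a median-split (ties to
low) Kaplan–Meier pair with the log-rank test, and the mean L2-to-event
diagnostic `|sigma(N(y_i, T_i)) - E_i|`. Kaplan–Meier, log-rank and
concordance go through lifelines; their test oracles are an independent hand
product-limit computation, per-event-time 2×2 tables, and exhaustive pair
enumeration.

## Synthetic cohorts

Each subject carries a latent risk (standard normal) that jointly drives:

* **CT**: soft-ellipse anatomy plus a tumor disc whose radius follows a
  *jittered* readout of the latent risk (sd 2.0 on the latent scale) —
  anatomical size is an imperfect surrogate of biology;
* **PET**: a dim copy of the anatomy plus a hotspot whose peak equals
  `gain * sigmoid(latent)` exactly and whose extent follows the latent
  directly — metabolism tracks biology, which is why PET adds prognostic
  value and what makes PET+CT fusion genuinely informative here;
* **clinical covariates**: age ~ Normal(60, 10) truncated to [18, 90], sex
  male with probability 0.79, T/N categories with latent-shifted log-odds,
  overall stage from a fixed monotone (T, N) map — marginals close to a
  predominantly stage-III/IV head-and-neck cohort;
* **outcomes**: Weibull proportional hazards, `S(t) =
  exp(-(rho t)^kappa e^{beta' x})` with kappa = 1.3, rho = 1/1200 per day,
  beta = (1.5, 0.25, 0.25) on (latent, standardized age, centered stage),
  endpoint-specific linear-predictor scalings (MFS 1.2, OS 1.0, PFS 0.9,
  RFS 0.6), inverse-transform sampling, and independent exponential
  censoring at 1/3500 per day. These defaults were calibrated once by Monte
  Carlo and frozen: ≈ 30% censoring and a true-linear-predictor concordance
  near 0.81.

What the phantoms do **not** emulate: scanner physics, attenuation and
partial-volume effects, multi-center batch effects, registration error,
anatomically realistic tumors, correlated endpoints. Passing desk-scale
checks therefore demonstrates that the pipeline recovers known signal under
its own assumptions — not clinical performance.

A cohort is a pure function of `(n, phantom params, hazard model, seed)`;
every random draw in the pipeline flows through named substreams of the root
seed, so any run report is exactly reproducible from its configuration.

## Reference workloads and problem sizes

The acceptance script and the test suite share the same seeded workloads:
closed-form loss fixtures; link-equivalence on 100 random tables (n ≤ 20);
finite-difference gradient checks; concordance vs exhaustive enumeration on
200 tied/censored fixtures (n ≤ 8); mask-plan exactness (147 of 196 at 75%)
and frequency uniformity over 10,000 plans; cross-attention vs brute-force
softmax; parameter recovery on covariate-only Weibull cohorts (n = 500,
400/100 split, 5 seeds); the full image pipeline on 200-subject phantom
cohorts (80/20 split, 30 pretraining and 50 fine-tuning epochs, PET+CT
fusion vs CT-only, 5 seeds); and bootstrap CI widths at n = 400 vs n = 50
(B = 1000, 20 seeds). These sizes keep a complete run in minutes on one CPU
core while leaving every qualitative conclusion (loss correctness, oracle
agreement, signal recovery, fusion ordering) intact.

## Known limitations

* The partial-likelihood denominator is exact within a minibatch only;
  small batches weaken the ranking signal per step (mitigated here by the
  linear head and the frozen evidence features).
* The evidence stream's threshold bank assumes intensity-coded pathology;
  modalities where lesions are hypo-intense would need a mirrored bank.
* The desk-scale linear head cannot express feature–time interactions; the
  time embedding then only shifts scores, leaving rankings time-constant.
* lifelines' concordance handles tied predictions/times per the standard
  definition (verified against scikit-survival on 2,646 random fixtures);
  other tie conventions would change third-decimal C values on tiny sets.
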