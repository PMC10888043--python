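# petctsurv

Multi-modal deep survival analysis for PET/CT imaging with structured
clinical text: masked-autoencoder (MAE) pretraining of per-modality
vision-transformer encoders, cross-attention PET/CT fusion, Q-Former
image–text fusion, and a time-indexed partial-likelihood loss with a sigmoid
relative-risk link — plus the full evaluation suite (Harrell's C with
bootstrap confidence intervals, Kaplan–Meier / log-rank risk stratification)
and a synthetic phantom-cohort generator with known hazard ground truth so
every stage is testable at desk scale on one CPU.

**Who it is for.** Researchers prototyping prognosis models on paired
PET/CT + clinical covariates (oncology time-to-event endpoints: OS, RFS,
MFS, PFS), and anyone who needs a transparent, framework-free reference
implementation of neural partial-likelihood training.

## The model

The hazard for covariates/images summarized as `y` is

    lambda(t, y) = lambda0(t) · sigmoid(N_theta(y, t))

where `N_theta` is a neural score that may depend on time. Training
maximizes the partial likelihood: for each event `i` at time `T_i` with risk
set `R(T_i) = {j : T_j >= T_i}`,

    l(theta) = -(1/N_ev) Σ_{i:E_i=1} [ log σ(N(y_i, T_i))
                                       - log Σ_{j∈R(T_i)} σ(N(y_j, T_i)) ]

The baseline hazard `lambda0` cancels, exactly as in Cox regression; with an
exponential link and time-invariant scores the loss *is* the Cox partial
likelihood (verified to 1e-10 in the tests). `y` is produced by frozen
MAE-pretrained ViT encoders, cross-attention fusion with CT as query/key and
PET as value, and a Q-Former bridging the fused image tokens with embedded
clinical fields (age decade, sex, T/N/M, stage). See `docs/methods.md` for
the full model description and all design decisions.

## Worked example

```python
import numpy as np
from petctsurv import (SurvivalTable, proposed_loss, cox_loss, harrell_c,
                       generate_cohort, bootstrap_ci)

# the hand-checkable fixture: two subjects, both events, all scores zero
table = SurvivalTable(["a", "b"], time=[1.0, 2.0], event=[1, 1])
proposed_loss(np.zeros((2, 2)), table)   # 0.34657359027997264  = ln(2)/2
cox_loss(np.zeros(2), table)             # 0.34657359027997264  (same: link-equivalence)

# a synthetic phantom cohort with known Weibull hazard
cohort = generate_cohort(n=300, seed=1)
os_table = cohort.survival_table("OS")   # 215 events of 300 (~30% censoring)
eta = cohort.true_linear_predictor("OS")
harrell_c(os_table, eta)                 # 0.803
ci = bootstrap_ci(harrell_c, os_table, eta, B=1000, seed=0)
# 95% CI: (0.771, 0.834)
```

The first two numbers are the closed-form value `ln(2)/2`: with both
subjects at score zero, the first event's term is `ln(1/2)` and the second
(a singleton risk set) contributes nothing. The concordance of the
generator's own linear predictor (~0.80) is the ceiling any trained model
can approach on these cohorts.

The full pipeline (simulate → pretrain → fine-tune → evaluate) runs from
Python via `petctsurv.run_experiment(ExperimentConfig(seed=0))` or from the
shell:

```bash
petctsurv simulate --n 200 --seed 0 --out cohort/
petctsurv run --seed 0 --out report.json
petctsurv ablate --axes modality --out ablation.csv
```

A desk-scale run (200 subjects, 64×64 phantoms, 30 pretraining + 50
fine-tuning epochs) takes about a minute per configuration on one CPU and
reaches held-out OS C-indices around 0.65–0.8 depending on the cohort seed,
with PET+CT cross-attention fusion consistently outranking CT-only — the
scaled-down analogue of the modality ablation. The `paper` scale preset
(`ExperimentConfig.paper_scale()`) carries the full-scale recipe (224×224
inputs, ViT-B encoders, 1000/300 epochs).

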