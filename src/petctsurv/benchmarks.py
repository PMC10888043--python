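"""Reference experiments at desk scale.

These are the package's own reproducibility workloads: each function runs a
complete, seeded experiment with the default study conditions and returns the
measured quantities. The test suite asserts properties of these results and
the acceptance script reports them; both call the same code.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit

from .autodiff import Tensor
from .pipeline import (ExperimentConfig, derive_seed, fit_risk_head,
                       predict_risk, prepare_inputs, run_finetune,
                       run_pretrain, split_cohort)
from .survival import SurvivalTable, bootstrap_ci, harrell_c
from .synthetic import (HazardModel, generate_cohort, simulate_clinical,
                        simulate_survival)

__all__ = [
    "simulate_covariate_cohort",
    "parameter_recovery",
    "end_to_end_fusion_comparison",
    "bootstrap_width_comparison",
]


def simulate_covariate_cohort(n: int, seed: int, endpoint: str = "OS",
                              model: HazardModel | None = None):
    """Covariates + outcomes only (no imaging): the tabular analogue of the
    phantom cohort, for risk-head and loss studies."""
    model = model or HazardModel()
    rng = np.random.default_rng(seed)
    lat = rng.normal(size=n)
    covs, times, events = [], [], []
    for i in range(n):
        rec = simulate_clinical(lat[i], int(rng.integers(2**31)))
        x = np.array([lat[i], (rec.age - 60.0) / 10.0,
                      rec.stage_ordinal - 2.0])
        out = simulate_survival(model, x, endpoint, int(rng.integers(2**31)))
        covs.append(x)
        times.append(out.time)
        events.append(out.event)
    table = SurvivalTable([f"s{i}" for i in range(n)], times, events, endpoint)
    return np.asarray(covs), table, model


def parameter_recovery(seed: int, n: int = 500, train_n: int = 400,
                       epochs: int = 150) -> dict:
    """Train a time-indexed MLP risk head under the sigmoid partial-likelihood
    loss on a known Weibull-PH cohort; compare held-out concordance with the
    true linear predictor's."""
    covs, table, model = simulate_covariate_cohort(
        n, derive_seed(seed, "recovery-cohort"))
    tr = np.arange(train_n)
    ev = np.arange(train_n, n)
    head, _ = fit_risk_head(covs[tr], table.subset(tr), epochs=epochs,
                            seed=derive_seed(seed, "recovery-fit"))
    tab_ev = table.subset(ev)
    t_med = float(np.median(tab_ev.time))
    scores = head(Tensor(covs[ev]), t_med).data
    c_model = harrell_c(tab_ev, expit(scores))
    eta = np.array([model.linear_predictor(x, table.endpoint)
                    for x in covs[ev]])
    c_true = harrell_c(tab_ev, eta)
    return {"c_model": c_model, "c_true": c_true,
            "censoring": 1.0 - table.event.mean()}


def _scalar_risk(cfg, model, encoders, cohort, idx, planes, endpoint="OS"):
    table = cohort.survival_table(endpoint).subset(idx)
    t_med = float(np.median(table.time))
    grid = np.unique(np.concatenate([table.time, [t_med]]))
    risk = predict_risk(cfg, model, encoders, cohort, idx, planes=planes,
                        times=grid)
    col = int(np.searchsorted(grid, t_med))
    return table, expit(risk.scores[:, col])


def end_to_end_fusion_comparison(seed: int, n: int = 200) -> dict:
    """Full image pipeline on one phantom cohort: MAE pretraining, then
    fine-tuning twice — PET+CT cross-attention fusion vs CT-only — evaluated
    on the held-out split for overall survival."""
    cfg = ExperimentConfig(seed=seed, n_subjects=n)
    cohort = generate_cohort(n, cfg.phantoms, cfg.hazard,
                             seed=derive_seed(seed, "cohort"))
    planes = prepare_inputs(cohort, cfg.preprocess, ("CT", "PET"))
    tr, ev = split_cohort(cohort, cfg.train_fraction, cfg.seed)
    encoders = {m: e for m, (e, _) in
                run_pretrain(cfg, cohort, planes=planes, train_idx=tr).items()}

    fusion_model, _ = run_finetune(cfg, cohort, encoders, planes=planes,
                                   train_idx=tr)
    tab, risk = _scalar_risk(cfg, fusion_model, encoders, cohort, ev, planes)
    c_fusion = harrell_c(tab, risk)

    cfg_ct = dataclasses.replace(cfg, modality="ct")
    ct_model, _ = run_finetune(cfg_ct, cohort, {"CT": encoders["CT"]},
                               planes=planes, train_idx=tr)
    tab, risk = _scalar_risk(cfg_ct, ct_model, {"CT": encoders["CT"]},
                             cohort, ev, planes)
    c_ct_only = harrell_c(tab, risk)
    return {"c_fusion": c_fusion, "c_ct_only": c_ct_only}


def bootstrap_width_comparison(seed: int, n_large: int = 400,
                               n_small: int = 50, B: int = 1000) -> dict:
    """Width of the percentile-bootstrap CI of Harrell's C at two cohort
    sizes drawn from the same generator."""
    out = {}
    for label, n in (("large", n_large), ("small", n_small)):
        covs, table, model = simulate_covariate_cohort(
            n, derive_seed(seed, f"bootwidth-{label}"))
        eta = np.array([model.linear_predictor(x, "OS") for x in covs])
        res = bootstrap_ci(harrell_c, table, eta, B=B,
                           seed=derive_seed(seed, f"bootci-{label}"))
        out[label] = res
    return {
        "width_large": out["large"].ci_upper - out["large"].ci_lower,
        "width_small": out["small"].ci_upper - out["small"].ci_lower,
        "estimate_large": out["large"].estimate,
        "contained": all(
            r.ci_lower <= r.estimate <= r.ci_upper for r in out.values()),
    }
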