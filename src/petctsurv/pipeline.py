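"""End-to-end orchestration: pretrain -> fusion fine-tune -> evaluation.

The run structure mirrors the two-stage training recipe: masked-autoencoder
pretraining produces one frozen encoder per modality; fine-tuning then trains
the fusion stack (cross-attention, clinical embeddings, Q-Former, risk head)
under the combined survival loss with a linear learning-rate warmup followed
by a constant rate. Evaluation computes, per endpoint, Harrell's C with a
percentile-bootstrap confidence interval, a median-split Kaplan-Meier /
log-rank analysis, and the mean L2 distance between the predicted event
probability at each subject's own follow-up time and the observed event
indicator.

Every random draw is seeded from the root seed through a named substream
registry, so a run report is a pure function of (config, cohort, seed).

Scale presets: ``desk`` (64 px phantoms, small transformer, minutes on one
CPU — the configuration all tests use) and ``paper`` (224 px inputs, ViT-B
encoders, 1000/300 epochs — the full-scale recipe, far beyond desk budgets).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .autodiff import AdamW, Tensor
from .fusion import FusionConfig, FusionModel, RiskHeadConfig
from .imaging import ModelInput, PreprocessConfig, bandpass_normalize, volume_to_input
from .survival import (CIndexResult, LossConfig, RiskOutput, SurvivalTable,
                       bootstrap_ci, combined_loss, harrell_c, km_curve,
                       l2_event_distance, log_rank, stratify)
from .synthetic import Cohort, HazardModel, PhantomParams, generate_cohort
from .vit_mae import ViTConfig, ViTEncoder, patchify, pretrain

__all__ = [
    "OptimSettings",
    "ExperimentConfig",
    "RunReport",
    "derive_seed",
    "prepare_inputs",
    "split_cohort",
    "run_pretrain",
    "run_finetune",
    "run_evaluate",
    "run_ablation_grid",
    "save_checkpoint",
    "load_checkpoint",
]

ENDPOINTS = ("OS", "RFS", "MFS", "PFS")


def derive_seed(root_seed: int, name: str) -> int:
    """Deterministic named substream seed (< 2**31) from the root seed."""
    h = int.from_bytes(hashlib.sha256(name.encode()).digest()[:4], "big")
    return int(np.random.SeedSequence(entropy=root_seed,
                                      spawn_key=(h,)).generate_state(1)[0] % (2**31))


@dataclass
class OptimSettings:
    epochs: int = 50
    batch_size: int = 256
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 5e-2
    warmup_epochs: int = 0

    def __post_init__(self) -> None:
        if self.warmup_epochs > self.epochs:
            raise ValueError("warmup must not exceed epochs")


@dataclass
class ExperimentConfig:
    seed: int = 0
    scale: str = "desk"                  # desk | paper
    endpoint: str = "OS"
    n_subjects: int = 200
    train_fraction: float = 0.8
    modality: str = "pet+ct"             # pet | ct | pet+ct
    vit: ViTConfig = field(default_factory=lambda: ViTConfig(
        input_side=64, patch_size=8, depth=2, width=32, heads=2,
        decoder_depth=1, decoder_width=16, decoder_heads=2, mlp_ratio=2.0))
    fusion: FusionConfig = field(default_factory=lambda: FusionConfig(
        d_model=32, n_queries=8, qformer_depth=2, heads=2))
    head: RiskHeadConfig = field(default_factory=lambda: RiskHeadConfig(
        time_embed_dim=16, mlp_widths=(), time_scale=4000.0))
    loss: LossConfig = field(default_factory=LossConfig)
    preprocess: PreprocessConfig = field(default_factory=lambda: PreprocessConfig(
        input_side=64))
    pretrain_opt: OptimSettings = field(default_factory=lambda: OptimSettings(
        epochs=30, batch_size=100, lr=1e-3, betas=(0.9, 0.95),
        weight_decay=1e-2))
    finetune_opt: OptimSettings = field(default_factory=lambda: OptimSettings(
        epochs=50, batch_size=16, lr=1e-2, betas=(0.9, 0.999),
        weight_decay=5e-2, warmup_epochs=5))
    mask_ratio: float = 0.75
    augment: bool = True        # dihedral (flip/rot90) augmentation in fine-tuning
    shift_augment: int = 8      # max |pixels| of random translation for the
                                # evidence-stream patches (0 disables)
    token_noise_sd: float = 0.0  # Gaussian noise on frozen tokens per step
    base_dropout: float = 0.5   # per-sample dropout of the Q-Former half of the
                                # pooled features during fine-tuning; forces the
                                # risk head to also use the patch-evidence half
    n_bootstrap: int = 1000
    phantoms: PhantomParams = field(default_factory=PhantomParams)
    hazard: HazardModel = field(default_factory=HazardModel)

    @classmethod
    def paper_scale(cls, **overrides) -> "ExperimentConfig":
        """The full-scale recipe: 224 px inputs, ViT-B, 1000/300 epochs."""
        cfg = cls(
            scale="paper",
            vit=ViTConfig.vit_b(224),
            fusion=FusionConfig(d_model=768, n_queries=8, qformer_depth=2,
                                heads=12),
            head=RiskHeadConfig(time_embed_dim=64, mlp_widths=(256, 64),
                                time_scale=4000.0),
            preprocess=PreprocessConfig(input_side=224),
            pretrain_opt=OptimSettings(epochs=1000, batch_size=128, lr=1e-3,
                                       betas=(0.9, 0.95), weight_decay=1e-2),
            finetune_opt=OptimSettings(epochs=300, batch_size=256, lr=1e-4,
                                       betas=(0.9, 0.999), weight_decay=5e-2,
                                       warmup_epochs=10),
        )
        return dataclasses.replace(cfg, **overrides)

    def fingerprint(self) -> str:
        blob = json.dumps(_to_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(_to_jsonable(asdict(self)), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "ExperimentConfig":
        with open(path) as f:
            raw = yaml.safe_load(f)
        return cls._from_dict(raw)

    @classmethod
    def _from_dict(cls, raw: dict) -> "ExperimentConfig":
        kw = dict(raw)
        for key, sub in (("vit", ViTConfig), ("fusion", FusionConfig),
                         ("head", RiskHeadConfig), ("loss", LossConfig),
                         ("preprocess", PreprocessConfig),
                         ("pretrain_opt", OptimSettings),
                         ("finetune_opt", OptimSettings),
                         ("phantoms", PhantomParams),
                         ("hazard", HazardModel)):
            if key in kw and isinstance(kw[key], dict):
                d = dict(kw[key])
                for tup_key in ("betas", "mlp_widths", "tumor_radius_range"):
                    if tup_key in d and isinstance(d[tup_key], list):
                        d[tup_key] = tuple(d[tup_key])
                if key == "hazard" and "beta" in d:
                    d["beta"] = np.asarray(d["beta"])
                kw[key] = sub(**d)
        return cls(**kw)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class RunReport:
    """Per-endpoint evaluation results, traceable to config + seed."""

    endpoint_results: dict[str, CIndexResult]
    logrank_p: dict[str, float]
    mean_l2: dict[str, float]
    config_fingerprint: str
    seed: int
    n_eval: int
    loss_trace: list[float] = field(default_factory=list)

    def to_json(self, path: str | None = None) -> dict:
        blob = {
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
            "n_eval": self.n_eval,
            "endpoints": {
                ep: {
                    "c_index": r.estimate,
                    "ci_lower": r.ci_lower,
                    "ci_upper": r.ci_upper,
                    "logrank_p": self.logrank_p[ep],
                    "mean_l2": self.mean_l2[ep],
                }
                for ep, r in self.endpoint_results.items()
            },
        }
        if path:
            with open(path, "w") as f:
                json.dump(blob, f, indent=2)
        return blob


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_inputs(cohort: Cohort, cfg: PreprocessConfig,
                   modalities: tuple[str, ...] = ("CT", "PET")) -> dict[str, np.ndarray]:
    """Preprocess every subject's volumes into (n, S, S) plane stacks."""
    out: dict[str, list[np.ndarray]] = {m: [] for m in modalities}
    for s in cohort.subjects:
        for m in modalities:
            vol = s.ct if m == "CT" else s.pet
            norm = bandpass_normalize(vol, cfg)
            out[m].append(volume_to_input(norm, s.mask, cfg).plane)
    return {m: np.stack(v) for m, v in out.items()}


def split_cohort(cohort: Cohort, train_fraction: float,
                 seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/eval index sets (shuffled by a derived seed)."""
    n = len(cohort)
    rng = np.random.default_rng(derive_seed(seed, "split"))
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def _modalities_for(modality: str) -> tuple[str, ...]:
    if modality == "pet+ct":
        return ("CT", "PET")
    if modality in ("pet", "ct"):
        return (modality.upper(),)
    raise ValueError(f"unknown modality {modality!r}")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_pretrain(config: ExperimentConfig, cohort: Cohort,
                 planes: dict[str, np.ndarray] | None = None,
                 train_idx: np.ndarray | None = None,
                 ) -> dict[str, tuple[ViTEncoder, list[float]]]:
    """Independent MAE runs per requested modality; encoders are then frozen."""
    mods = _modalities_for(config.modality)
    planes = planes or prepare_inputs(cohort, config.preprocess, mods)
    out = {}
    for m in mods:
        stack = planes[m]
        if train_idx is not None:
            stack = stack[train_idx]
        enc, _, trace = pretrain(
            stack, config.vit,
            epochs=config.pretrain_opt.epochs,
            batch_size=config.pretrain_opt.batch_size,
            lr=config.pretrain_opt.lr,
            betas=config.pretrain_opt.betas,
            weight_decay=config.pretrain_opt.weight_decay,
            mask_ratio=config.mask_ratio,
            seed=derive_seed(config.seed, f"pretrain:{m}"),
        )
        out[m] = (enc, trace)
    return out


def _dihedral(plane: np.ndarray, k: int) -> np.ndarray:
    """The 8 symmetries of the square: k//4 flips, k%4 quarter-turns."""
    p = plane[::-1] if k >= 4 else plane
    return np.rot90(p, k % 4)


def _encode_frozen(encoders: dict[str, ViTEncoder], planes: dict[str, np.ndarray],
                   idx: np.ndarray, patch_size: int,
                   augmentations: int = 1) -> dict[str, tuple[Tensor, Tensor]]:
    """Frozen-encoder tokens and raw pixel patches per modality (no grads).

    With ``augmentations > 1`` the leading axis enumerates dihedral variants
    of each plane (variant 0 = identity): tokens (A, n, L, width), patches
    (A, n, L, patch_size**2).
    """
    from .vit_mae import patchify
    out = {}
    for m, enc in encoders.items():
        tok_variants, patch_variants = [], []
        for k in range(augmentations):
            stack = [_dihedral(p, k) for p in planes[m][idx]]
            patches = np.stack([patchify(p, patch_size) for p in stack])
            tok_variants.append(enc(Tensor(patches)).data)
            patch_variants.append(patches)
        if augmentations == 1:
            out[m] = (Tensor(tok_variants[0]), Tensor(patch_variants[0]))
        else:
            out[m] = (Tensor(np.stack(tok_variants)),
                      Tensor(np.stack(patch_variants)))
    return out


def _warmup_schedule(warmup: int):
    if warmup <= 0:
        return None
    return lambda step: min(1.0, step / float(warmup))


def run_finetune(config: ExperimentConfig, cohort: Cohort,
                 encoders: dict[str, ViTEncoder],
                 planes: dict[str, np.ndarray] | None = None,
                 train_idx: np.ndarray | None = None,
                 instance: int = 0) -> tuple[FusionModel, list[float]]:
    """Train fusion + Q-Former + risk head under the combined survival loss.

    Encoders stay frozen: their token sequences are computed once and treated
    as constants. Full-batch steps, linear warmup then constant lr; aborts on
    NaN loss.
    """
    mods = _modalities_for(config.modality)
    planes = planes or prepare_inputs(cohort, config.preprocess, mods)
    if train_idx is None:
        train_idx = np.arange(len(cohort))
    table = cohort.survival_table(config.endpoint).subset(train_idx)
    records = [cohort.subjects[i].clinical for i in train_idx]
    n_aug = 8 if config.augment else 1
    frozen = _encode_frozen(encoders, planes, train_idx, config.vit.patch_size,
                            augmentations=n_aug)
    ct_tok, ct_patch = frozen.get("CT", (None, None))
    pet_tok, pet_patch = frozen.get("PET", (None, None))
    if config.modality == "pet":
        mode = "single_pet"
    elif config.modality == "ct":
        mode = "single_ct"
    else:
        mode = config.fusion.mode
    fusion_cfg = dataclasses.replace(config.fusion, mode=mode)

    rng = np.random.default_rng(
        derive_seed(config.seed, f"finetune-init:{instance}"))
    model = FusionModel(fusion_cfg, config.head, config.vit.width, rng,
                        patch_dim=config.vit.patch_dim)
    # freeze the pooled-feature standardization from the initial model's
    # training-set features (identity augmentation)
    def ident(tok):
        return None if tok is None else (Tensor(tok.data[0]) if n_aug > 1 else tok)
    init_pooled = model.pooled_features(
        ident(ct_tok), ident(pet_tok), records,
        ct_patches=ident(ct_patch), pet_patches=ident(pet_patch)).data
    model.set_feature_scaler(init_pooled)
    steps_per_epoch = int(np.ceil(len(table) / min(config.finetune_opt.batch_size,
                                                   len(table))))
    opt = AdamW(model.parameters(), lr=config.finetune_opt.lr,
                betas=config.finetune_opt.betas,
                weight_decay=config.finetune_opt.weight_decay,
                lr_schedule=_warmup_schedule(
                    config.finetune_opt.warmup_epochs * steps_per_epoch))

    n = len(table)
    bs = min(config.finetune_opt.batch_size, n)
    shuffle_rng = np.random.default_rng(
        derive_seed(config.seed, f"finetune-shuffle:{instance}"))
    train_planes = {m: planes[m][train_idx] for m in mods}
    trace: list[float] = []
    for _ in range(config.finetune_opt.epochs):
        order = shuffle_rng.permutation(n)
        aug = (shuffle_rng.integers(n_aug, size=n) if n_aug > 1
               else np.zeros(n, dtype=int))
        epoch_losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            sub = table.subset(idx)
            if sub.n_events == 0:  # partial likelihood undefined on this batch
                continue
            grid = np.unique(sub.time[sub.event == 1])
            sel = ((aug[idx], idx) if n_aug > 1 else idx)

            def pick(tok):
                if tok is None:
                    return None
                t = tok[sel]
                if config.token_noise_sd > 0:
                    t = t + Tensor(shuffle_rng.normal(
                        0, config.token_noise_sd, t.shape))
                return t

            # evidence-stream patches: freshly translated each step so the
            # per-patch gate cannot memorize subject-specific patch patterns
            shift = config.shift_augment
            shifts = (shuffle_rng.integers(-shift, shift + 1,
                                           size=(len(idx), 2))
                      if shift > 0 else None)

            def evidence(mod):
                if mod not in train_planes:
                    return None
                if shifts is None:
                    return pick(ct_patch if mod == "CT" else pet_patch)
                arr = []
                for j, i in enumerate(idx):
                    p = _dihedral(train_planes[mod][i], int(aug[i]))
                    p = np.roll(np.roll(p, shifts[j, 0], 0), shifts[j, 1], 1)
                    arr.append(patchify(p, config.vit.patch_size))
                return Tensor(np.stack(arr))

            pooled = model.pooled_features(
                pick(ct_tok), pick(pet_tok), [records[i] for i in idx],
                ct_patches=evidence("CT"), pet_patches=evidence("PET"))
            if config.base_dropout > 0:
                d = model.fusion_cfg.d_model
                keep = (shuffle_rng.random(len(idx)) >= config.base_dropout)
                mask = np.ones((len(idx), 2 * d))
                mask[:, :d] = keep[:, None] / (1.0 - config.base_dropout)
                pooled = pooled * Tensor(mask)
            scores = model.risk_scores(pooled, grid)
            own = model.head(pooled, sub.time)
            loss = combined_loss(scores, sub, config.loss, own_scores=own)
            if not np.isfinite(loss.data):
                raise FloatingPointError("fine-tuning diverged: NaN loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    return model, trace


def fit_risk_head(features: np.ndarray, table: SurvivalTable,
                  head_cfg: RiskHeadConfig | None = None, *, epochs: int = 200,
                  batch_size: int = 128, lr: float = 1e-2,
                  weight_decay: float = 1e-3, seed: int = 0,
                  loss_cfg: LossConfig | None = None):
    """Train a time-indexed MLP risk head on fixed feature vectors.

    The direct neural analogue of a Cox fit: features (n, d) in, pre-link
    scores N(x, t) out, optimized under the combined survival loss. Used for
    covariate-only models and parameter-recovery checks.
    """
    from .fusion import RiskHead

    features = np.asarray(features, dtype=np.float64)
    head_cfg = head_cfg or RiskHeadConfig(
        time_embed_dim=16, mlp_widths=(32, 16),
        time_scale=float(table.time.max()))
    loss_cfg = loss_cfg or LossConfig(use_focal=False)
    rng = np.random.default_rng(seed)
    head = RiskHead(features.shape[1], head_cfg, rng)
    n = len(table)
    bs = min(batch_size, n)
    steps_per_epoch = int(np.ceil(n / bs))
    opt = AdamW(head.parameters(), lr=lr, betas=(0.9, 0.999),
                weight_decay=weight_decay,
                lr_schedule=_warmup_schedule(5 * steps_per_epoch))
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            sub = table.subset(idx)
            if sub.n_events == 0:
                continue
            grid = np.unique(sub.time[sub.event == 1])
            pooled = Tensor(features[idx])
            m = grid.size
            rep = pooled.reshape(len(idx), 1, -1) + Tensor(np.zeros((1, m, 1)))
            scores = head(rep.reshape(len(idx) * m, -1),
                          np.tile(grid, len(idx))).reshape(len(idx), m)
            own = head(pooled, sub.time)
            loss = combined_loss(scores, sub, loss_cfg, own_scores=own)
            if not np.isfinite(loss.data):
                raise FloatingPointError("risk-head fit diverged")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        trace.append(float(np.mean(losses)))
    return head, trace


def predict_risk(config: ExperimentConfig, model: FusionModel,
                 encoders: dict[str, ViTEncoder], cohort: Cohort,
                 idx: np.ndarray, planes: dict[str, np.ndarray] | None = None,
                 times: np.ndarray | None = None) -> RiskOutput:
    """Pre-link scores for the selected subjects on a time grid.

    When the config enables augmentation, scores are averaged over the eight
    dihedral variants of each plane (test-time augmentation), matching the
    augmentation used in fine-tuning and reducing prediction variance.
    """
    mods = _modalities_for(config.modality)
    planes = planes or prepare_inputs(cohort, config.preprocess, mods)
    n_aug = 8 if config.augment else 1
    frozen = _encode_frozen(encoders, planes, idx, config.vit.patch_size,
                            augmentations=n_aug)
    ct_tok, ct_patch = frozen.get("CT", (None, None))
    pet_tok, pet_patch = frozen.get("PET", (None, None))
    records = [cohort.subjects[i].clinical for i in idx]
    if times is None:
        times = np.unique(cohort.survival_table(config.endpoint).subset(idx).time)
    acc = None
    for k in range(n_aug):
        def var(tok):
            if tok is None:
                return None
            return Tensor(tok.data[k]) if n_aug > 1 else tok
        pooled = model.pooled_features(var(ct_tok), var(pet_tok), records,
                                       ct_patches=var(ct_patch),
                                       pet_patches=var(pet_patch))
        scores = model.risk_scores(pooled, times).data
        acc = scores if acc is None else acc + scores
    return RiskOutput(scores=acc / n_aug, times=np.asarray(times, dtype=float))


def run_evaluate(config: ExperimentConfig, model: FusionModel,
                 encoders: dict[str, ViTEncoder], cohort: Cohort,
                 eval_idx: np.ndarray, train_idx: np.ndarray | None = None,
                 planes: dict[str, np.ndarray] | None = None,
                 loss_trace: list[float] | None = None) -> RunReport:
    """C-index + bootstrap CI, median-split K-M/log-rank, and mean L2 per endpoint.

    The scalar ranking score of subject j is sigma(N(y_j, t_med)) at the
    evaluation-set median follow-up time t_med.
    """
    from scipy.special import expit

    eval_idx = np.asarray(eval_idx)
    if train_idx is not None:
        train_ids = {cohort.subjects[i].subject_id for i in train_idx}
        eval_ids = {cohort.subjects[i].subject_id for i in eval_idx}
        if train_ids & eval_ids:
            raise ValueError("train and eval subject ids overlap")
    mods = _modalities_for(config.modality)
    planes = planes or prepare_inputs(cohort, config.preprocess, mods)

    results, logrank_p, mean_l2 = {}, {}, {}
    for ep in ENDPOINTS:
        table = cohort.survival_table(ep).subset(eval_idx)
        t_med = float(np.median(table.time))
        grid = np.unique(np.concatenate([table.time, [t_med]]))
        risk = predict_risk(config, model, encoders, cohort, eval_idx,
                            planes=planes, times=grid)
        col = int(np.searchsorted(grid, t_med))
        risk_scalar = expit(risk.scores[:, col])
        results[ep] = bootstrap_ci(
            harrell_c, table, risk_scalar, B=config.n_bootstrap,
            seed=derive_seed(config.seed, f"bootstrap:{ep}"))
        try:
            labels, _ = stratify(risk_scalar)
            lo, hi = np.flatnonzero(labels == "low"), np.flatnonzero(labels == "high")
            _, p = log_rank(table.subset(lo), table.subset(hi))
        except ValueError:
            p = float("nan")
        logrank_p[ep] = p
        _, mean_l2[ep] = l2_event_distance(risk, table)
    return RunReport(
        endpoint_results=results, logrank_p=logrank_p, mean_l2=mean_l2,
        config_fingerprint=config.fingerprint(), seed=config.seed,
        n_eval=len(eval_idx), loss_trace=loss_trace or [],
    )


def run_experiment(config: ExperimentConfig,
                   cohort: Cohort | None = None) -> RunReport:
    """Full pipeline on a (generated or given) cohort: split, pretrain,
    fine-tune, evaluate."""
    cohort = cohort or generate_cohort(config.n_subjects, config.phantoms,
                                       config.hazard,
                                       seed=derive_seed(config.seed, "cohort"))
    mods = _modalities_for(config.modality)
    planes = prepare_inputs(cohort, config.preprocess, mods)
    train_idx, eval_idx = split_cohort(cohort, config.train_fraction, config.seed)
    enc = run_pretrain(config, cohort, planes=planes, train_idx=train_idx)
    encoders = {m: e for m, (e, _) in enc.items()}
    model, trace = run_finetune(config, cohort, encoders, planes=planes,
                                train_idx=train_idx)
    return run_evaluate(config, model, encoders, cohort, eval_idx,
                        train_idx=train_idx, planes=planes, loss_trace=trace)


def run_ablation_grid(base: ExperimentConfig, axes: dict[str, list],
                      cohort: Cohort | None = None) -> pd.DataFrame:
    """One run per grid cell over subsets of {modality, fusion, qformer, loss}.

    All cells share the cohort and the root seed; the result frame has one
    row per configuration and one C-index column per endpoint.
    """
    allowed = {"modality", "fusion", "qformer", "loss"}
    if not axes or not set(axes) <= allowed:
        raise ValueError(f"axes must be a nonempty subset of {allowed}")
    cohort = cohort or generate_cohort(base.n_subjects, base.phantoms,
                                       base.hazard,
                                       seed=derive_seed(base.seed, "cohort"))
    import itertools
    keys = list(axes)
    rows = []
    for combo in itertools.product(*(axes[k] for k in keys)):
        cfg = base
        label = {}
        for k, v in zip(keys, combo):
            label[k] = str(v)
            if k == "modality":
                cfg = dataclasses.replace(cfg, modality=v)
            elif k == "fusion":
                cfg = dataclasses.replace(
                    cfg, fusion=dataclasses.replace(cfg.fusion, mode=v))
            elif k == "qformer":
                cfg = dataclasses.replace(
                    cfg, fusion=dataclasses.replace(cfg.fusion, use_qformer=v))
            elif k == "loss":
                cfg = dataclasses.replace(cfg, loss=v)
        report = run_experiment(cfg, cohort=cohort)
        row = {**label}
        for ep in ENDPOINTS:
            r = report.endpoint_results[ep]
            row[ep] = r.estimate
            row[f"{ep}_ci"] = f"({r.ci_lower:.3f}, {r.ci_upper:.3f})"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path: str, module, config: ExperimentConfig) -> None:
    """Single-file checkpoint: weights + config + seed."""
    state = module.state_dict()
    meta = json.dumps(_to_jsonable(asdict(config)))
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path: str, module) -> ExperimentConfig:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        state = {k: z[k] for k in z.files if k != "__meta__"}
    module.load_state_dict(state)
    return ExperimentConfig._from_dict(meta)
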