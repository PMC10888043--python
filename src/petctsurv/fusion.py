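"""Multi-modal fusion: PET/CT cross-attention, clinical-text Q-Former, risk head.

Image fusion follows the asymmetric cross-attention design: the CT stream is
linearly projected into the query and key, the PET stream into the value
(PET carries both metabolic and anatomical signal, CT mostly anatomy), and
the fused tokens are ``softmax(Q K^T / sqrt(d_k)) V`` followed by a residual
feed-forward block. Swapping the roles, plain concatenation, and
single-modality self-attention are available as ablation modes.

Image-text fusion is a Q-Former: a small set of learnable query tokens that
(1) self-attend jointly with the embedded clinical-text tokens, (2)
cross-attend into the fused image tokens, (3) pass through a feed-forward
block, repeated for a few layers. Clinical fields are embedded as one token
per field via lookup tables — never as ordinal numeric codes.

The risk head maps pooled query tokens plus a sinusoidal embedding of
normalized time to the *pre-link* scalar score N(y, t); the sigmoid is
applied inside the survival loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concatenate, softmax
from .nn import (FeedForward, LayerNorm, Linear, Module, MultiHeadAttention,
                 sinusoidal_embedding)
from .synthetic import ClinicalRecord, N_STAGES, STAGES, T_STAGES
from .vit_mae import FeatureSequence

__all__ = [
    "FusionConfig",
    "TextTokens",
    "RiskHeadConfig",
    "CrossAttentionFuser",
    "ClinicalEmbedder",
    "QFormer",
    "ConcatFC",
    "RiskHead",
    "FusionModel",
]

FUSION_MODES = ("cross_qk_ct_v_pet", "cross_qk_pet_v_ct", "concat_fc",
                "single_pet", "single_ct")

CLINICAL_FIELDS = ("age_bin", "sex", "t_stage", "n_stage", "m_stage",
                   "overall_stage")
_VOCAB = {
    "age_bin": [str(d) for d in range(1, 10)],  # age // 10 for ages 18..90
    "sex": ["male", "female"],
    "t_stage": list(T_STAGES),
    "n_stage": list(N_STAGES),
    "m_stage": ["M0"],
    "overall_stage": list(STAGES),
}


@dataclass
class FusionConfig:
    mode: str = "cross_qk_ct_v_pet"
    use_qformer: bool = True
    n_queries: int = 8
    qformer_depth: int = 2
    d_model: int = 128
    heads: int = 4
    mlp_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.mode not in FUSION_MODES:
            raise ValueError(f"mode must be one of {FUSION_MODES}")
        if self.n_queries < 1:
            raise ValueError("n_queries must be >= 1")


@dataclass
class TextTokens:
    """One embedding token per clinical field, F x d."""

    tokens: np.ndarray | Tensor
    fields: tuple[str, ...] = CLINICAL_FIELDS

    def __post_init__(self) -> None:
        data = self.tokens.data if isinstance(self.tokens, Tensor) else self.tokens
        if data.ndim < 2 or data.shape[-2] != len(self.fields):
            raise ValueError("need one token per clinical field")
        if not np.isfinite(data).all():
            raise ValueError("non-finite text embeddings")


@dataclass
class RiskHeadConfig:
    time_embed_dim: int = 16
    mlp_widths: tuple[int, ...] = (64, 32)
    time_scale: float = 4000.0   # max follow-up (days) used to normalize t

    def __post_init__(self) -> None:
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")


class CrossAttentionFuser(Module):
    """softmax(QK^T/sqrt(d_k))V with Q,K from one stream, V from the other.

    Single-head by construction (the fusion step is a single attention map);
    output = A + FFN(LN(A)) where A is the attended value projection.
    ``cross_attention_fuse(x, x)`` with tied projections reduces to
    self-attention on x, which implements the single-modality ablations.
    """

    def __init__(self, d_model: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0):
        self.d_model = d_model
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.ln = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, int(d_model * mlp_ratio), rng)

    def __call__(self, qk_stream: Tensor, v_stream: Tensor) -> Tensor:
        if qk_stream.shape != v_stream.shape:
            raise ValueError(
                f"stream shapes differ: {qk_stream.shape} vs {v_stream.shape}")
        q, k = self.wq(qk_stream), self.wk(qk_stream)
        v = self.wv(v_stream)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_model))
        if not np.all(np.isfinite(logits.data)):
            raise FloatingPointError("non-finite attention logits")
        attended = softmax(logits, axis=-1) @ v
        return attended + self.ffn(self.ln(attended))

    def attention_matrix(self, qk_stream: Tensor) -> np.ndarray:
        """The row-stochastic attention map (for diagnostics/tests)."""
        q, k = self.wq(qk_stream), self.wk(qk_stream)
        logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_model))
        return softmax(logits, axis=-1).data


class ClinicalEmbedder(Module):
    """Lookup-table embeddings, one token per structured clinical field."""

    def __init__(self, d_model: int, rng: np.random.Generator):
        self.d_model = d_model
        self.tables = [
            Tensor(rng.normal(0, 0.5, (len(_VOCAB[f]), d_model)),
                   requires_grad=True)
            for f in CLINICAL_FIELDS
        ]

    @staticmethod
    def field_indices(record: ClinicalRecord) -> list[int]:
        if not (18 <= record.age <= 90):
            raise ValueError(f"age {record.age} below/above supported range")
        values = {
            "age_bin": str(record.age // 10),
            "sex": record.sex,
            "t_stage": record.t_stage,
            "n_stage": record.n_stage,
            "m_stage": record.m_stage,
            "overall_stage": record.overall_stage,
        }
        idx = []
        for f in CLINICAL_FIELDS:
            vocab = _VOCAB[f]
            if values[f] not in vocab:
                raise ValueError(f"{f} value {values[f]!r} outside vocabulary")
            idx.append(vocab.index(values[f]))
        return idx

    def __call__(self, record: ClinicalRecord) -> TextTokens:
        idx = self.field_indices(record)
        toks = concatenate(
            [self.tables[i][j].reshape(1, self.d_model)
             for i, j in enumerate(idx)], axis=0)
        return TextTokens(tokens=toks)

    def batch(self, records: list[ClinicalRecord]) -> Tensor:
        """(B, F, d) token tensor for a list of records."""
        rows = [self(r).tokens.reshape(1, len(CLINICAL_FIELDS), self.d_model)
                for r in records]
        return concatenate(rows, axis=0)


class QFormerBlock(Module):
    def __init__(self, d_model: int, heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 2.0):
        self.ln_self = LayerNorm(d_model)
        self.self_attn = MultiHeadAttention(d_model, heads, rng)
        self.ln_cross = LayerNorm(d_model)
        self.cross_attn = MultiHeadAttention(d_model, heads, rng)
        self.ln_ffn = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, int(d_model * mlp_ratio), rng)

    def __call__(self, queries: Tensor, text: Tensor, image: Tensor) -> Tensor:
        nq = queries.shape[-2]
        qt = concatenate([queries, text], axis=-2)
        h = self.ln_self(qt)
        attended = self.self_attn(h, h, h)
        queries = queries + attended[..., :nq, :]
        queries = queries + self.cross_attn(self.ln_cross(queries), image, image)
        return queries + self.ffn(self.ln_ffn(queries))


class QFormer(Module):
    """Learnable query tokens bridging image features and clinical text."""

    def __init__(self, cfg: FusionConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.queries = Tensor(rng.normal(0, 0.5, (cfg.n_queries, cfg.d_model)),
                              requires_grad=True)
        self.blocks = [QFormerBlock(cfg.d_model, cfg.heads, rng, cfg.mlp_ratio)
                       for _ in range(cfg.qformer_depth)]

    def __call__(self, image_feats: Tensor, text: Tensor) -> Tensor:
        """image_feats (B, L, d) or (L, d); text likewise; returns query tokens."""
        if not np.isfinite(image_feats.data).all():
            raise ValueError("non-finite image features")
        q = self.queries
        if image_feats.ndim == 3:
            B = image_feats.shape[0]
            q = q.reshape(1, *q.shape) + Tensor(np.zeros((B, 1, 1)))
        for blk in self.blocks:
            q = blk(q, text, image_feats)
        return q


class ConcatFC(Module):
    """Ablation fusion: mean-pooled image and text vectors, concat, linear+GELU."""

    def __init__(self, d_model: int, rng: np.random.Generator,
                 d_out: int | None = None):
        self.fc = Linear(2 * d_model, d_out or d_model, rng)

    def __call__(self, image_feats: Tensor, text: Tensor) -> Tensor:
        img = image_feats.mean(axis=-2)
        txt = text.mean(axis=-2)
        return self.fc(concatenate([img, txt], axis=-1)).gelu()


class RiskHead(Module):
    """Pre-link scalar risk N(y, t) from pooled fused tokens and time.

    Time is injected as a sinusoidal embedding of ``t / time_scale``; the
    output is unlinked — the survival loss applies the sigmoid.
    """

    def __init__(self, d_model: int, cfg: RiskHeadConfig,
                 rng: np.random.Generator):
        self.cfg = cfg
        d_in = d_model + cfg.time_embed_dim
        dims = [d_in, *cfg.mlp_widths]
        self.layers = [Linear(a, b, rng) for a, b in zip(dims[:-1], dims[1:])]
        self.out = Linear(dims[-1], 1, rng)

    def __call__(self, pooled: Tensor, t: np.ndarray | float) -> Tensor:
        """pooled: (B, d) fused feature vectors; t: scalar or (B,) days."""
        t = np.asarray(t, dtype=np.float64)
        if np.any(t < 0):
            raise ValueError("negative time")
        if t.ndim == 0:
            t = np.full(pooled.shape[0] if pooled.ndim == 2 else 1, float(t))
        emb = sinusoidal_embedding(t / self.cfg.time_scale, self.cfg.time_embed_dim)
        if pooled.ndim == 1:
            pooled = pooled.reshape(1, -1)
        x = concatenate([pooled, Tensor(emb)], axis=-1)
        for layer in self.layers:
            x = layer(x).gelu()
        return self.out(x).reshape(-1)


class FusionModel(Module):
    """Fusion stack from frozen encoder tokens to risk scores.

    Holds the cross-attention fuser, clinical embedder, Q-Former (or
    concat+FC), and the risk head; the per-modality encoders stay outside
    (frozen after pretraining), so this is exactly the trainable part of
    fine-tuning.
    """

    def __init__(self, fusion_cfg: FusionConfig, head_cfg: RiskHeadConfig,
                 encoder_width: int, rng: np.random.Generator,
                 patch_dim: int | None = None):
        self.fusion_cfg = fusion_cfg
        self.patch_dim = patch_dim or encoder_width
        self.proj = (Linear(encoder_width, fusion_cfg.d_model, rng)
                     if encoder_width != fusion_cfg.d_model else None)
        self.fuser = CrossAttentionFuser(fusion_cfg.d_model, rng,
                                         fusion_cfg.mlp_ratio)
        self.embedder = ClinicalEmbedder(fusion_cfg.d_model, rng)
        self.qformer = (QFormer(fusion_cfg, rng) if fusion_cfg.use_qformer
                        else None)
        self.concat_fc = (None if fusion_cfg.use_qformer
                          else ConcatFC(fusion_cfg.d_model, rng))
        # low-level evidence stream: a FIXED bank of soft intensity-threshold
        # features on raw pixel patches, mean-pooled over patches. Each
        # channel is "soft area above threshold theta" — the classic
        # thresholded-volume biomarker (metabolic tumor volume in PET). The
        # bank is a frozen featurizer, like a radiomics panel: the risk head
        # learns how to weight it, not what it measures.
        d = fusion_cfg.d_model
        alphas = np.array([4.0, 8.0, 16.0])[np.arange(d) % 3]
        thetas = np.linspace(0.1, 0.9, d)
        w = (np.tile(alphas / self.patch_dim, (self.patch_dim, 1))
             + rng.normal(0, 0.02, (self.patch_dim, d)))
        self.evidence_weight = Tensor(w)                 # frozen
        self.evidence_bias = Tensor(-alphas * thetas)    # frozen
        # frozen per-dim standardization of the pooled features (train-set
        # statistics, set once before fine-tuning): heterogeneous feature
        # scales otherwise interact badly with uniform weight decay
        self.feature_mu = Tensor(np.zeros(2 * d))
        self.feature_sd = Tensor(np.ones(2 * d))
        # head consumes [pooled queries ; mean patch evidence]
        self.head = RiskHead(2 * fusion_cfg.d_model, head_cfg, rng)

    def fuse_images(self, ct_tokens: Tensor | None,
                    pet_tokens: Tensor | None) -> Tensor:
        if self.proj is not None:
            ct_tokens = self.proj(ct_tokens) if ct_tokens is not None else None
            pet_tokens = self.proj(pet_tokens) if pet_tokens is not None else None
        return self._fuse_projected(ct_tokens, pet_tokens)

    def _fuse_projected(self, ct_tokens: Tensor | None,
                        pet_tokens: Tensor | None) -> Tensor:
        mode = self.fusion_cfg.mode
        if mode == "cross_qk_ct_v_pet":
            return self.fuser(ct_tokens, pet_tokens)
        if mode == "cross_qk_pet_v_ct":
            return self.fuser(pet_tokens, ct_tokens)
        if mode == "single_pet":
            return self.fuser(pet_tokens, pet_tokens)
        if mode == "single_ct":
            return self.fuser(ct_tokens, ct_tokens)
        if mode == "concat_fc":
            both = [t for t in (ct_tokens, pet_tokens) if t is not None]
            return concatenate(both, axis=-2)
        raise ValueError(mode)

    def _value_stream(self, ct: Tensor | None, pet: Tensor | None) -> Tensor:
        mode = self.fusion_cfg.mode
        if mode in ("cross_qk_ct_v_pet", "single_pet"):
            return pet
        if mode in ("cross_qk_pet_v_ct", "single_ct"):
            return ct
        both = [t for t in (ct, pet) if t is not None]
        return concatenate(both, axis=-2)

    def patch_evidence(self, patches: Tensor) -> Tensor:
        """Fixed soft-threshold features on raw pixels, averaged over patches.

        The multi-scale low-level stream: a tumor occupies a handful of
        patches, and statistics like "fraction of high-uptake patches" need a
        per-patch nonlinearity *before* pooling — encoder features mixed by
        attention lose them when attention is still diffuse. Raw pixel
        patches keep that evidence directly accessible.
        """
        return ((patches @ self.evidence_weight + self.evidence_bias)
                .gelu().mean(axis=-2))

    def pooled_features(self, ct_tokens: Tensor | None, pet_tokens: Tensor | None,
                        records: list[ClinicalRecord],
                        ct_patches: Tensor | None = None,
                        pet_patches: Tensor | None = None) -> Tensor:
        """[mean Q-Former queries ; mean patch evidence] feature vector.

        ``*_tokens`` are frozen-encoder features driving the cross-attention
        and Q-Former streams; ``*_patches`` are the raw pixel patches of the
        same planes feeding the low-level evidence stream (they default to
        the encoder tokens when not supplied).
        """
        fused = self.fuse_images(ct_tokens, pet_tokens)
        text = self.embedder.batch(records)
        if ct_patches is None and pet_patches is None:
            ct_patches, pet_patches = ct_tokens, pet_tokens
        evidence = self.patch_evidence(
            self._value_stream(ct_patches, pet_patches))
        if self.qformer is not None:
            base = self.qformer(fused, text).mean(axis=-2)
        else:
            base = self.concat_fc(fused, text)
        pooled = concatenate([base, evidence], axis=-1)
        return (pooled - self.feature_mu) / self.feature_sd

    def set_feature_scaler(self, pooled: np.ndarray, eps: float = 1e-6) -> None:
        """Freeze per-dim standardization from (unscaled) training features."""
        self.feature_mu.data = pooled.mean(axis=0)
        self.feature_sd.data = pooled.std(axis=0) + eps

    def risk_scores(self, pooled: Tensor, times: np.ndarray) -> Tensor:
        """Score every subject at every time: returns (B, len(times))."""
        times = np.atleast_1d(np.asarray(times, dtype=np.float64))
        B = pooled.shape[0]
        m = times.size
        # tile subjects over times as one flat batch through the MLP
        rep = pooled.reshape(B, 1, -1) + Tensor(np.zeros((1, m, 1)))
        flat = rep.reshape(B * m, pooled.shape[-1])
        t_flat = np.tile(times, B)
        return self.head(flat, t_flat).reshape(B, m)
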