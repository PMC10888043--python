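"""Patch-transformer encoders and masked-autoencoder pretraining.

PET and CT get architecturally identical but weight-independent encoders
(dual-stream). Pretraining is the masked-autoencoder task: a random 75% of
patches is hidden, the encoder sees only the visible patches (with positional
embeddings indexed by their *original* grid positions), and a light decoder
reconstructs the masked patches. The reconstruction target is each patch
standardized to zero mean / unit variance, and the loss is mean squared error
over masked positions only.

One mask plan is drawn per optimization step and shared across the batch;
masks are drawn per step, so over training every patch position is masked
with equal frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import AdamW, Tensor, concatenate
from .imaging import ModelInput
from .nn import LayerNorm, Linear, Module, TransformerBlock

__all__ = [
    "ViTConfig",
    "MaskPlan",
    "FeatureSequence",
    "patchify",
    "unpatchify",
    "plan_mask",
    "ViTEncoder",
    "MAEDecoder",
    "mae_reconstruction_loss",
    "pretrain",
]


@dataclass
class ViTConfig:
    """Encoder/decoder geometry. Defaults are the desk-scale configuration;
    ``vit_b()`` gives the full-scale variant."""

    input_side: int = 64
    patch_size: int = 8
    depth: int = 4
    width: int = 128
    heads: int = 4
    decoder_depth: int = 2
    decoder_width: int = 64
    decoder_heads: int = 4
    mlp_ratio: float = 4.0

    def __post_init__(self) -> None:
        if self.input_side % self.patch_size:
            raise ValueError("input_side must be divisible by patch_size")
        if self.width % self.heads or self.decoder_width % self.decoder_heads:
            raise ValueError("width must be divisible by heads")

    @property
    def n_patches(self) -> int:
        return (self.input_side // self.patch_size) ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size**2

    @classmethod
    def vit_b(cls, input_side: int = 224) -> "ViTConfig":
        return cls(input_side=input_side, patch_size=16, depth=12, width=768,
                   heads=12, decoder_depth=8, decoder_width=512, decoder_heads=16)


@dataclass
class MaskPlan:
    n_patches: int
    masked_idx: np.ndarray
    visible_idx: np.ndarray
    ratio: float

    def __post_init__(self) -> None:
        m = set(self.masked_idx.tolist())
        v = set(self.visible_idx.tolist())
        if m & v or (m | v) != set(range(self.n_patches)):
            raise ValueError("masked/visible must partition the patch indices")
        if len(self.masked_idx) != int(np.floor(self.ratio * self.n_patches)):
            raise ValueError("|masked| must equal floor(ratio * n_patches)")


@dataclass
class FeatureSequence:
    """L x d token matrix with a modality tag — the lingua franca between
    encoders, fusion blocks and the risk head."""

    tokens: np.ndarray
    modality_tag: str  # PET | CT | fused | query

    def __post_init__(self) -> None:
        self.tokens = np.asarray(self.tokens, dtype=np.float64)
        if self.tokens.ndim != 2 or self.tokens.shape[0] < 1:
            raise ValueError("tokens must be a nonempty L x d matrix")
        if not np.isfinite(self.tokens).all():
            raise ValueError("non-finite tokens")


def patchify(plane: np.ndarray | ModelInput, patch_size: int) -> np.ndarray:
    """(S, S) plane -> (L, p^2) row-major patches; exact inverse is unpatchify."""
    if isinstance(plane, ModelInput):
        plane = plane.plane
    plane = np.asarray(plane)
    side = plane.shape[0]
    if plane.ndim != 2 or plane.shape[1] != side or side % patch_size:
        raise ValueError(f"plane side must be square and divisible by {patch_size}")
    g = side // patch_size
    return (plane.reshape(g, patch_size, g, patch_size)
            .transpose(0, 2, 1, 3).reshape(g * g, patch_size**2))


def unpatchify(patches: np.ndarray, patch_size: int) -> np.ndarray:
    patches = np.asarray(patches)
    g = int(np.sqrt(patches.shape[0]))
    if g * g != patches.shape[0] or patches.shape[1] != patch_size**2:
        raise ValueError("patches do not form a square grid")
    return (patches.reshape(g, g, patch_size, patch_size)
            .transpose(0, 2, 1, 3).reshape(g * patch_size, g * patch_size))


def plan_mask(n_patches: int, ratio: float, seed: int | np.random.Generator) -> MaskPlan:
    """Uniform random subset of floor(ratio * n_patches) masked indices."""
    if not (0.0 <= ratio < 1.0):
        raise ValueError("mask ratio must lie in [0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_masked = int(np.floor(ratio * n_patches))
    perm = rng.permutation(n_patches)
    return MaskPlan(n_patches=n_patches,
                    masked_idx=np.sort(perm[:n_masked]),
                    visible_idx=np.sort(perm[n_masked:]),
                    ratio=ratio)


class ViTEncoder(Module):
    """Transformer encoder over patch tokens with learned positional embeddings.

    ``positions`` index the *original* patch grid, so encoding only the
    visible subset remains position-faithful during MAE.
    """

    def __init__(self, config: ViTConfig, rng: np.random.Generator):
        self.config = config
        self.patch_embed = Linear(config.patch_dim, config.width, rng)
        self.pos_embed = Tensor(rng.normal(0, 0.02, (config.n_patches, config.width)),
                                requires_grad=True)
        self.blocks = [TransformerBlock(config.width, config.heads, rng,
                                        mlp_ratio=config.mlp_ratio)
                       for _ in range(config.depth)]
        self.ln = LayerNorm(config.width)

    def __call__(self, patches: Tensor | np.ndarray,
                 positions: np.ndarray | None = None) -> Tensor:
        """patches: (..., L, p^2); positions: (L,) grid indices (default all)."""
        x = patches if isinstance(patches, Tensor) else Tensor(patches)
        L = x.shape[-2]
        if positions is None:
            positions = np.arange(L)
        positions = np.asarray(positions)
        if positions.shape != (L,):
            raise ValueError("positions must match the token count")
        x = self.patch_embed(x) + self.pos_embed[positions]
        for blk in self.blocks:
            x = blk(x)
        return self.ln(x)

    def encode_plane(self, plane: np.ndarray | ModelInput) -> FeatureSequence:
        """Full-sequence encoding of one plane (no masking, no gradients)."""
        patches = patchify(plane, self.config.patch_size)
        tokens = self(Tensor(patches)).data
        tag = plane.modality if isinstance(plane, ModelInput) else "CT"
        return FeatureSequence(tokens=tokens, modality_tag=tag)


class MAEDecoder(Module):
    """Light decoder: embeds encoder tokens, appends a learned mask token at
    each masked position, and regresses per-patch pixels."""

    def __init__(self, config: ViTConfig, rng: np.random.Generator):
        self.config = config
        self.embed = Linear(config.width, config.decoder_width, rng)
        self.mask_token = Tensor(rng.normal(0, 0.02, (config.decoder_width,)),
                                 requires_grad=True)
        self.pos_embed = Tensor(
            rng.normal(0, 0.02, (config.n_patches, config.decoder_width)),
            requires_grad=True)
        self.blocks = [TransformerBlock(config.decoder_width, config.decoder_heads,
                                        rng, mlp_ratio=config.mlp_ratio)
                       for _ in range(config.decoder_depth)]
        self.ln = LayerNorm(config.decoder_width)
        self.head = Linear(config.decoder_width, config.patch_dim, rng)

    def __call__(self, encoded: Tensor, plan: MaskPlan) -> Tensor:
        """encoded: (B, L_vis, width) -> (B, L, p^2) in [visible; masked] order."""
        B = encoded.shape[0]
        vis = self.embed(encoded) + self.pos_embed[plan.visible_idx]
        n_masked = len(plan.masked_idx)
        mask_tok = (self.mask_token.reshape(1, 1, -1)
                    + self.pos_embed[plan.masked_idx].reshape(1, n_masked, -1))
        mask_tok = mask_tok + Tensor(np.zeros((B, n_masked, 1)))  # broadcast to batch
        x = concatenate([vis, mask_tok], axis=1)
        for blk in self.blocks:
            x = blk(x)
        return self.head(self.ln(x))


def _standardize_patches(target: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    mu = target.mean(axis=-1, keepdims=True)
    sd = target.std(axis=-1, keepdims=True)
    return (target - mu) / (sd + eps)


def mae_reconstruction_loss(decoded: Tensor | np.ndarray, target: np.ndarray,
                            plan: MaskPlan, order: str = "grid"):
    """MSE over masked patches, targets standardized per patch.

    ``decoded`` either covers all patch positions in grid order
    (``order='grid'``) or is laid out ``[visible; masked]`` as produced by
    :class:`MAEDecoder` (``order='shuffled'``). ``target`` is always the full
    (..., L, p^2) patch array in grid order.
    """
    if len(plan.masked_idx) == 0:
        raise ValueError("empty mask set: reconstruction loss undefined")
    target = _standardize_patches(np.asarray(target, dtype=np.float64))
    if order == "grid":
        dec_masked = (decoded[..., plan.masked_idx, :] if isinstance(decoded, Tensor)
                      else Tensor(np.asarray(decoded)[..., plan.masked_idx, :]))
    elif order == "shuffled":
        n_vis = len(plan.visible_idx)
        dec = decoded if isinstance(decoded, Tensor) else Tensor(np.asarray(decoded))
        dec_masked = dec[..., n_vis:, :]
    else:
        raise ValueError(f"unknown order {order!r}")
    tgt_masked = Tensor(target[..., plan.masked_idx, :])
    diff = dec_masked - tgt_masked
    loss = (diff * diff).mean()
    return loss if isinstance(decoded, Tensor) else float(loss.data)


def pretrain(planes: np.ndarray, config: ViTConfig, *, epochs: int = 30,
             batch_size: int = 64, lr: float = 1e-3,
             betas: tuple[float, float] = (0.9, 0.95),
             weight_decay: float = 1e-2, mask_ratio: float = 0.75,
             seed: int = 0) -> tuple[ViTEncoder, MAEDecoder, list[float]]:
    """MAE-pretrain one modality's encoder on a stack of planes (N, S, S).

    Returns the encoder, the decoder and the per-epoch mean reconstruction
    loss. Deterministic given the seed. Aborts on NaN loss.
    """
    planes = np.asarray(planes, dtype=np.float64)
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("need a nonempty stack of (N, S, S) planes")
    init_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                            spawn_key=(0,)))
    run_rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                           spawn_key=(1,)))
    encoder = ViTEncoder(config, init_rng)
    decoder = MAEDecoder(config, init_rng)
    opt = AdamW(encoder.parameters() + decoder.parameters(), lr=lr,
                betas=betas, weight_decay=weight_decay)
    patches = np.stack([patchify(p, config.patch_size) for p in planes])
    n = patches.shape[0]
    trace: list[float] = []
    for _ in range(epochs):
        order = run_rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            plan = plan_mask(config.n_patches, mask_ratio, run_rng)
            batch = patches[idx]
            enc = encoder(Tensor(batch[:, plan.visible_idx]), plan.visible_idx)
            dec = decoder(enc, plan)
            # decoder emits [visible; masked]; compare against matching targets
            loss = mae_reconstruction_loss(dec, batch, plan, order="shuffled")
            if not np.isfinite(loss.data):
                raise FloatingPointError("pretraining diverged: NaN loss")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(float(loss.data))
        trace.append(float(np.mean(epoch_losses)))
    return encoder, decoder, trace
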