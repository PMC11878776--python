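"""Three-branch hierarchical encoder with partial freezing and a fusion head.

One branch per patch scale (P_l, P_m, P_s), parameter-independent (no weight
sharing). Each branch of the built-in "tiny" backbone maps a 224x224x3 patch
to a D-dimensional embedding through

    block statistics -> Linear (patch embedding) -> B residual MLP blocks
    -> LayerNorm

where "block statistics" is a fixed, parameter-free featurization: the patch
is divided into an 8x8 grid and each cell contributes per-channel mean,
standard deviation and mean absolute deviation (8*8*3*3 = 576 features).
Mean captures tone and low-frequency structure; the dispersion statistics
capture fine texture that survives only at near-native resolution, which is
what the small-scale branch exists to see.

The fusion head concatenates the branch embeddings and applies
Linear -> GELU -> Dropout -> Linear to produce four subtype logits.

Fine-tuning freezes the patch-embedding stage together with the first
``floor(n_blocks * freeze_ratio)`` blocks of every branch (60% of a 24-block
encoder = 14 blocks); with a zero count nothing is frozen, so a 0% freeze
ratio means a fully trainable model. Frozen parameters are guaranteed
bit-identical across optimization because the optimizer never touches them.

Everything is plain numpy with hand-derived gradients and a decoupled
weight-decay Adam (AdamW) optimizer, deterministic under a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
from scipy.special import erf

SCALES = ("l", "m", "s")
N_CLASSES = 4
FEATURE_GRID = 8
PATCH_PX = 224
_CELL = PATCH_PX // FEATURE_GRID  # 28
N_FEATURES = FEATURE_GRID * FEATURE_GRID * 3 * 3  # 576
_LN_EPS = 1e-5


# ---------------------------------------------------------------------------
# Backbone registry


@dataclass(frozen=True)
class BackboneSpec:
    """Contract of a patch encoder: any 224x224x3 image -> length-D vector."""

    name: str
    embed_dim: int
    n_blocks: int
    input_px: int = PATCH_PX
    block_hidden: int | None = None  # default 2 * embed_dim
    requires_weights: bool = False

    def __post_init__(self) -> None:
        if self.embed_dim < 1 or self.n_blocks < 1:
            raise ValueError("embed_dim and n_blocks must be >= 1")


BACKBONES: dict[str, BackboneSpec] = {
    # CPU-friendly trainable encoder used by every test.
    "tiny": BackboneSpec("tiny", embed_dim=64, n_blocks=4),
    # Hook for externally supplied foundation-model weights (ViT-L geometry:
    # 24 blocks, D=1024). Weights are gated and never shipped; building this
    # backbone without supplying them raises.
    "uni-adapter": BackboneSpec("uni-adapter", embed_dim=1024, n_blocks=24, requires_weights=True),
}


def get_backbone(name: str) -> BackboneSpec:
    try:
        return BACKBONES[name]
    except KeyError:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}") from None


def register_backbone(spec: BackboneSpec) -> None:
    BACKBONES[spec.name] = spec


# ---------------------------------------------------------------------------
# Arithmetic of the freezing strategy


def frozen_block_count(n_blocks: int, freeze_ratio: float) -> int:
    """Number of encoder blocks frozen at a given ratio: floor(B * ratio).

    At 60% of a 24-block encoder this is 14 blocks.
    """
    if not 0.0 <= freeze_ratio <= 1.0:
        raise ValueError(f"freeze_ratio must lie in [0, 1], got {freeze_ratio}")
    if n_blocks < 0:
        raise ValueError("n_blocks must be >= 0")
    return int(math.floor(n_blocks * freeze_ratio))


# ---------------------------------------------------------------------------
# Featurization (fixed structural transform; carries no parameters)


def featurize(patch: np.ndarray) -> np.ndarray:
    """Block statistics of one patch -> (576,) float32 feature vector."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.shape != (PATCH_PX, PATCH_PX, 3):
        raise ValueError(f"expected a ({PATCH_PX}, {PATCH_PX}, 3) patch, got {patch.shape}")
    x = patch / 255.0
    g = x.reshape(FEATURE_GRID, _CELL, FEATURE_GRID, _CELL, 3)
    mean = g.mean(axis=(1, 3))
    centered = g - mean[:, None, :, None, :]
    std = np.sqrt((centered**2).mean(axis=(1, 3)))
    mad = np.abs(centered).mean(axis=(1, 3))
    return np.stack([mean, std, mad], axis=-1).reshape(-1).astype(np.float32)


def featurize_batch(patches: Iterable[np.ndarray]) -> np.ndarray:
    return np.stack([featurize(p) for p in patches])


# ---------------------------------------------------------------------------
# Model


@dataclass(frozen=True)
class HiModelConfig:
    """Architecture + freezing configuration.

    ``scales`` selects which branches exist; single-scale variants (used by
    the ablation experiments) simply restrict it, and the fusion input width
    is ``len(scales) * embed_dim``.
    """

    backbone: BackboneSpec = field(default_factory=lambda: get_backbone("tiny"))
    freeze_ratio: float = 0.6
    fusion_hidden: int | None = None
    dropout: float = 0.25
    n_classes: int = N_CLASSES
    scales: tuple[str, ...] = SCALES
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freeze_ratio <= 1.0:
            raise ValueError("freeze_ratio must lie in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not self.scales or any(s not in SCALES for s in self.scales):
            raise ValueError(f"scales must be a non-empty subset of {SCALES}")
        if len(set(self.scales)) != len(self.scales):
            raise ValueError("scales must not repeat")


def _gelu(x: np.ndarray) -> np.ndarray:
    return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))


def _gelu_grad(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0))) + x * np.exp(-0.5 * x * x) / math.sqrt(
        2.0 * math.pi
    )


class HiModel:
    """The multi-branch classifier: parameters, forward pass, gradients."""

    def __init__(self, config: HiModelConfig):
        spec = config.backbone
        if spec.requires_weights:
            raise NotImplementedError(
                f"backbone {spec.name!r} needs externally supplied weights; register a "
                "BackboneSpec without requires_weights once they are available"
            )
        self.config = config
        d = spec.embed_dim
        h_block = spec.block_hidden or 2 * d
        h_fusion = config.fusion_hidden or d
        rng = np.random.default_rng(config.seed)

        def w(shape):
            return rng.normal(0.0, 0.02, size=shape)

        self.params: dict[str, np.ndarray] = {}
        for s in config.scales:
            self.params[f"{s}.embed.W"] = w((N_FEATURES, d))
            self.params[f"{s}.embed.b"] = np.zeros(d)
            for i in range(spec.n_blocks):
                self.params[f"{s}.block{i}.W1"] = w((d, h_block))
                self.params[f"{s}.block{i}.b1"] = np.zeros(h_block)
                self.params[f"{s}.block{i}.W2"] = w((h_block, d))
                self.params[f"{s}.block{i}.b2"] = np.zeros(d)
            self.params[f"{s}.norm.g"] = np.ones(d)
            self.params[f"{s}.norm.b"] = np.zeros(d)
        fused = len(config.scales) * d
        self.params["head.W1"] = w((fused, h_fusion))
        self.params["head.b1"] = np.zeros(h_fusion)
        self.params["head.W2"] = w((h_fusion, config.n_classes))
        self.params["head.b2"] = np.zeros(config.n_classes)

        # Per-scale feature standardization buffers (fit on training data).
        self.feat_mean = {s: np.zeros(N_FEATURES) for s in config.scales}
        self.feat_sd = {s: np.ones(N_FEATURES) for s in config.scales}

        self.frozen: set[str] = set()
        self.apply_freeze(frozen_block_count(spec.n_blocks, config.freeze_ratio))

    # -- freezing ----------------------------------------------------------

    def apply_freeze(self, count: int) -> None:
        """Freeze the embedding stage and the first ``count`` blocks of every
        branch. ``count == 0`` leaves the whole model trainable (the
        embedding is frozen only together with at least one block)."""
        if count > self.config.backbone.n_blocks:
            raise ValueError(
                f"cannot freeze {count} blocks of a {self.config.backbone.n_blocks}-block encoder"
            )
        if count < 0:
            raise ValueError("count must be >= 0")
        frozen: set[str] = set()
        if count > 0:
            for s in self.config.scales:
                frozen.update({f"{s}.embed.W", f"{s}.embed.b"})
                for i in range(count):
                    frozen.update(
                        f"{s}.block{i}.{p}" for p in ("W1", "b1", "W2", "b2")
                    )
        self.frozen = frozen

    @property
    def trainable(self) -> set[str]:
        return set(self.params) - self.frozen

    def frozen_parameter_names(self) -> list[str]:
        return sorted(self.frozen)

    def trainable_parameter_names(self) -> list[str]:
        return sorted(self.trainable)

    # -- feature normalization --------------------------------------------

    def fit_feature_norm(self, feats: dict[str, np.ndarray]) -> None:
        """Fit per-feature standardization on (training) features."""
        for s in self.config.scales:
            x = np.asarray(feats[s], dtype=np.float64)
            self.feat_mean[s] = x.mean(axis=0)
            self.feat_sd[s] = np.maximum(x.std(axis=0), 1e-6)

    # -- forward / backward ------------------------------------------------

    def _branch_forward(self, s: str, x: np.ndarray, cache: dict | None) -> np.ndarray:
        p = self.params
        h = x @ p[f"{s}.embed.W"] + p[f"{s}.embed.b"]
        hs, us, activs = [h], [], []
        for i in range(self.config.backbone.n_blocks):
            u = h @ p[f"{s}.block{i}.W1"] + p[f"{s}.block{i}.b1"]
            a = _gelu(u)
            h = h + a @ p[f"{s}.block{i}.W2"] + p[f"{s}.block{i}.b2"]
            us.append(u)
            activs.append(a)
            hs.append(h)
        mu = h.mean(axis=1, keepdims=True)
        var = h.var(axis=1, keepdims=True)
        xhat = (h - mu) / np.sqrt(var + _LN_EPS)
        y = p[f"{s}.norm.g"] * xhat + p[f"{s}.norm.b"]
        if cache is not None:
            cache[s] = {"x": x, "hs": hs, "us": us, "as": activs, "xhat": xhat, "var": var}
        return y

    def _standardize(self, s: str, feats: np.ndarray) -> np.ndarray:
        return (np.asarray(feats, dtype=np.float64) - self.feat_mean[s]) / self.feat_sd[s]

    def forward_features(
        self,
        feats: dict[str, np.ndarray],
        training: bool = False,
        rng: np.random.Generator | None = None,
        cache: dict | None = None,
    ) -> np.ndarray:
        """Logits (n, n_classes) from per-scale feature matrices (n, 576)."""
        p = self.params
        ys = []
        branch_cache: dict | None = {} if cache is not None else None
        for s in self.config.scales:
            ys.append(self._branch_forward(s, self._standardize(s, feats[s]), branch_cache))
        f = np.concatenate(ys, axis=1)
        u1 = f @ p["head.W1"] + p["head.b1"]
        a1 = _gelu(u1)
        if training and self.config.dropout > 0.0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = 1.0 - self.config.dropout
            mask = (rng.random(a1.shape) < keep) / keep
        else:
            mask = np.ones_like(a1)
        d = a1 * mask
        z = d @ p["head.W2"] + p["head.b2"]
        if cache is not None:
            cache.update({"branches": branch_cache, "f": f, "u1": u1, "mask": mask, "d": d})
        return z

    def forward(self, patches: dict[str, np.ndarray]) -> np.ndarray:
        """Logits from raw image batches {scale: (n, 224, 224, 3)}.

        Evaluation mode (no dropout): deterministic.
        """
        feats = {s: featurize_batch(patches[s]) for s in self.config.scales}
        return self.forward_features(feats)

    def loss_and_grads(
        self,
        feats: dict[str, np.ndarray],
        labels: np.ndarray,
        rng: np.random.Generator,
    ) -> tuple[float, dict[str, np.ndarray]]:
        """Cross-entropy loss and gradients for one (training-mode) batch."""
        cache: dict = {}
        z = self.forward_features(feats, training=True, rng=rng, cache=cache)
        n = z.shape[0]
        z_shift = z - z.max(axis=1, keepdims=True)
        expz = np.exp(z_shift)
        probs = expz / expz.sum(axis=1, keepdims=True)
        loss = float(-np.mean(np.log(probs[np.arange(n), labels] + 1e-300)))

        grads: dict[str, np.ndarray] = {}
        dz = probs.copy()
        dz[np.arange(n), labels] -= 1.0
        dz /= n

        p = self.params
        grads["head.W2"] = cache["d"].T @ dz
        grads["head.b2"] = dz.sum(axis=0)
        dd = dz @ p["head.W2"].T
        da1 = dd * cache["mask"]
        du1 = da1 * _gelu_grad(cache["u1"])
        grads["head.W1"] = cache["f"].T @ du1
        grads["head.b1"] = du1.sum(axis=0)
        df = du1 @ p["head.W1"].T

        d_embed = self.config.backbone.embed_dim
        for k, s in enumerate(self.config.scales):
            dy = df[:, k * d_embed : (k + 1) * d_embed]
            bc = cache["branches"][s]
            xhat, var = bc["xhat"], bc["var"]
            grads[f"{s}.norm.g"] = (dy * xhat).sum(axis=0)
            grads[f"{s}.norm.b"] = dy.sum(axis=0)
            dxhat = dy * p[f"{s}.norm.g"]
            inv_sd = 1.0 / np.sqrt(var + _LN_EPS)
            dh = inv_sd * (
                dxhat
                - dxhat.mean(axis=1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=1, keepdims=True)
            )
            for i in reversed(range(self.config.backbone.n_blocks)):
                h_in, u, a = bc["hs"][i], bc["us"][i], bc["as"][i]
                grads[f"{s}.block{i}.b2"] = dh.sum(axis=0)
                grads[f"{s}.block{i}.W2"] = a.T @ dh
                da = dh @ p[f"{s}.block{i}.W2"].T
                du = da * _gelu_grad(u)
                grads[f"{s}.block{i}.b1"] = du.sum(axis=0)
                grads[f"{s}.block{i}.W1"] = h_in.T @ du
                dh = dh + du @ p[f"{s}.block{i}.W1"].T
            grads[f"{s}.embed.W"] = bc["x"].T @ dh
            grads[f"{s}.embed.b"] = dh.sum(axis=0)
        return loss, grads

    def predict_logits(self, feats: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluation-mode logits (deterministic)."""
        return self.forward_features(feats, training=False)

    # -- persistence -------------------------------------------------------

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def save(self, path: str | Path) -> None:
        """Checkpoint: config, parameters, norm buffers, frozen-name list."""
        meta = {
            "backbone_spec": dataclasses.asdict(self.config.backbone),
            "freeze_ratio": self.config.freeze_ratio,
            "fusion_hidden": self.config.fusion_hidden,
            "dropout": self.config.dropout,
            "n_classes": self.config.n_classes,
            "scales": list(self.config.scales),
            "seed": self.config.seed,
            "frozen": self.frozen_parameter_names(),
        }
        arrays = {f"param:{k}": v for k, v in self.params.items()}
        for s in self.config.scales:
            arrays[f"featmean:{s}"] = self.feat_mean[s]
            arrays[f"featsd:{s}"] = self.feat_sd[s]
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "HiModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            config = HiModelConfig(
                backbone=BackboneSpec(**meta["backbone_spec"]),
                freeze_ratio=meta["freeze_ratio"],
                fusion_hidden=meta["fusion_hidden"],
                dropout=meta["dropout"],
                n_classes=meta["n_classes"],
                scales=tuple(meta["scales"]),
                seed=meta["seed"],
            )
            model = cls(config)
            for k in list(model.params):
                model.params[k] = data[f"param:{k}"]
            for s in config.scales:
                model.feat_mean[s] = data[f"featmean:{s}"]
                model.feat_sd[s] = data[f"featsd:{s}"]
            model.frozen = set(meta["frozen"])
        return model


class AdamW:
    """Adam with decoupled weight decay; never updates frozen parameters."""

    def __init__(
        self,
        model: HiModel,
        lr: float,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.model = model
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        b1, b2 = self.betas
        self.t += 1
        for name in sorted(self.model.trainable):
            g = grads[name]
            self.m[name] = b1 * self.m[name] + (1 - b1) * g
            self.v[name] = b2 * self.v[name] + (1 - b2) * g * g
            mhat = self.m[name] / (1 - b1**self.t)
            vhat = self.v[name] / (1 - b2**self.t)
            p = self.model.params[name]
            p -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p)
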