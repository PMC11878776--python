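"""Weakly supervised training of the hierarchical classifier.

Patch triples carry no annotation of their own: every triple inherits the
molecular-subtype label of its slide. Class imbalance is handled at the
patch level by random undersampling at per-class rates (defaults: MMRd 70%,
NSMP 50%, the two minority classes untouched), applied to training folds
only. Optimization is mini-batch cross-entropy with AdamW at the reference
hyperparameters (lr 2e-4, batch size 12, dropout 0.25); batches are drawn by
a fresh seeded shuffle per epoch-equivalent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import AdamW, HiModel
from .synthetic import SUBTYPES

logger = logging.getLogger(__name__)

DEFAULT_BALANCE_RATES = {"MMRd": 0.70, "NSMP": 0.50, "p53abn": 1.0, "POLEmut": 1.0}

#: Canonical class index used for labels and logits everywhere.
CLASS_INDEX = {c: i for i, c in enumerate(SUBTYPES)}


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    ``iterations`` defaults to the reference schedule (20 000 steps per
    fold); desk-scale runs on synthetic cohorts use 500 (see
    :mod:`hiwsi.pipeline` profiles).
    """

    lr: float = 2e-4
    batch_size: int = 12
    iterations: int = 20000
    dropout: float = 0.25
    weight_decay: float = 0.01
    seed: int = 0
    balance_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BALANCE_RATES)
    )

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be >= 0")
        if self.batch_size < 1 or self.iterations < 0:
            raise ValueError("batch_size must be >= 1 and iterations >= 0")
        for cls, rate in self.balance_rates.items():
            if not 0.0 < rate <= 1.0:
                raise ValueError(f"balance rate for {cls} must lie in (0, 1], got {rate}")


def inherit_labels(triple_index: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Attach each triple's slide subtype and patient id (weak supervision).

    ``triple_index`` needs a ``slide_id`` column; ``manifest`` needs
    ``slide_id``, ``patient_id`` and ``subtype``. Slides labeled ``unknown``
    are excluded with a warning; a triple whose slide is absent from the
    manifest is an error.
    """
    lookup = manifest.set_index("slide_id")
    unknown_ids = set(triple_index["slide_id"]) - set(lookup.index)
    if unknown_ids:
        raise ValueError(f"triples reference slides absent from the manifest: {sorted(unknown_ids)}")
    out = triple_index.merge(
        manifest[["slide_id", "patient_id", "subtype"]], on="slide_id", how="left"
    )
    n_unknown = int((out["subtype"] == "unknown").sum())
    if n_unknown:
        warnings.warn(f"excluding {n_unknown} patches from slides with unknown subtype")
        out = out[out["subtype"] != "unknown"].reset_index(drop=True)
    counts = out["subtype"].value_counts().to_dict()
    logger.info("labeled patch counts per class: %s", counts)
    return out


def balance_patches(
    patches: pd.DataFrame, rates: dict[str, float] | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-class random undersampling without replacement.

    Each class present is independently subsampled to ``round(rate * n)``;
    classes missing from ``rates`` (or with rate 1.0) are untouched. Row
    order of the survivors is preserved; deterministic under ``seed``.
    """
    rates = dict(DEFAULT_BALANCE_RATES) if rates is None else rates
    for cls, rate in rates.items():
        if not 0.0 < rate <= 1.0:
            raise ValueError(f"balance rate for {cls} must lie in (0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    keep = np.zeros(len(patches), dtype=bool)
    positions = np.arange(len(patches))
    for cls in sorted(patches["subtype"].unique()):
        cls_pos = positions[(patches["subtype"] == cls).to_numpy()]
        rate = rates.get(cls, 1.0)
        if rate == 1.0:
            keep[cls_pos] = True
            continue
        k = int(round(rate * len(cls_pos)))
        chosen = rng.choice(len(cls_pos), size=k, replace=False)
        keep[cls_pos[np.sort(chosen)]] = True
    return patches.iloc[keep].reset_index(drop=True)


def train(
    model: HiModel,
    feats: dict[str, np.ndarray],
    labels: np.ndarray,
    config: TrainConfig = TrainConfig(),
) -> tuple[HiModel, np.ndarray]:
    """Run ``config.iterations`` AdamW steps on shuffled mini-batches.

    ``feats`` maps each model scale to an (N, 576) feature matrix; ``labels``
    are class indices (see :data:`CLASS_INDEX`). Fits the model's feature
    standardization on this training set first. Returns the model and the
    per-step loss trace. Fully deterministic under ``config.seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} patches, got {n}")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires at least 2 classes present")
    for s in model.config.scales:
        if feats[s].shape[0] != n:
            raise ValueError("feature matrices and labels must have equal length")

    model.fit_feature_norm(feats)
    std = {s: model._standardize(s, feats[s]) for s in model.config.scales}
    # Pre-standardized features are passed through identity buffers below.
    saved_mean = {s: model.feat_mean[s].copy() for s in model.config.scales}
    saved_sd = {s: model.feat_sd[s].copy() for s in model.config.scales}
    for s in model.config.scales:
        model.feat_mean[s] = np.zeros_like(saved_mean[s])
        model.feat_sd[s] = np.ones_like(saved_sd[s])

    rng = np.random.default_rng(config.seed)
    opt = AdamW(model, lr=config.lr, weight_decay=config.weight_decay)
    trace = np.empty(config.iterations)
    order = rng.permutation(n)
    ptr = 0
    try:
        for step in range(config.iterations):
            if ptr + config.batch_size > n:
                order = rng.permutation(n)
                ptr = 0
            idx = order[ptr : ptr + config.batch_size]
            ptr += config.batch_size
            batch = {s: std[s][idx] for s in model.config.scales}
            loss, grads = model.loss_and_grads(batch, labels[idx], rng)
            opt.step(grads)
            trace[step] = loss
            if step % 100 == 0:
                logger.info("step %d loss %.4f lr %.2g seed %d", step, loss, config.lr, config.seed)
    finally:
        for s in model.config.scales:
            model.feat_mean[s] = saved_mean[s]
            model.feat_sd[s] = saved_sd[s]
    return model, trace
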