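"""End-to-end orchestration: tile -> hierarchy -> featurize -> CV -> metrics.

A single top-level seed fans out to per-stage seeds through a stable
stage-name hash, so one knob reproduces the full run; every artifact is
stamped with a hash of the run configuration, and loaders refuse artifacts
produced under a different configuration unless explicitly overridden.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluate import (
    FoldSplit,
    SlidePrediction,
    aggregate_slide,
    classification_metrics,
    fold_ci,
    interp_roc,
    kfold_split,
    macro_auroc,
    roc_auc,
    roc_curve_points,
)
from .hierarchy import HierarchyConfig, build_triple
from .model import HiModel, HiModelConfig, featurize, get_backbone
from .synthetic import SUBTYPES
from .tiling import FilterConfig, SlideRecord, TileScanStats, _scan_arrays, load_mask, load_slide_image, read_manifest
from .training import CLASS_INDEX, TrainConfig, balance_patches, inherit_labels, train

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a stage seed from the top-level seed and the stage name."""
    digest = hashlib.blake2b(f"{seed}:{stage}".encode("utf-8"), digest_size=4).digest()
    return int.from_bytes(digest, "big") & 0x7FFFFFFF


@dataclass(frozen=True)
class RunConfig:
    """Complete, serializable description of one cross-validation run."""

    manifest: str
    workdir: str
    filter: FilterConfig = field(default_factory=FilterConfig)
    hierarchy: HierarchyConfig = field(default_factory=HierarchyConfig)
    backbone: str = "tiny"
    freeze_ratio: float = 0.6
    fusion_hidden: int | None = None
    dropout: float = 0.25
    scales: tuple[str, ...] = ("l", "m", "s")
    train: TrainConfig = field(default_factory=lambda: TrainConfig(iterations=500))
    k: int = 5
    seed: int = 0
    ci_method: str = "normal"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scales"] = list(self.scales)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "filter" in d and isinstance(d["filter"], dict):
            d["filter"] = FilterConfig(**d["filter"])
        if "hierarchy" in d and isinstance(d["hierarchy"], dict):
            h = dict(d["hierarchy"])
            if isinstance(h.get("color_filter"), dict):
                h["color_filter"] = FilterConfig(**h["color_filter"])
            d["hierarchy"] = HierarchyConfig(**h)
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "scales" in d:
            d["scales"] = tuple(d["scales"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode("utf-8")
        return hashlib.sha256(payload).hexdigest()[:12]

    def model_config(self, seed: int, scales: tuple[str, ...] | None = None) -> HiModelConfig:
        return HiModelConfig(
            backbone=get_backbone(self.backbone),
            freeze_ratio=self.freeze_ratio,
            fusion_hidden=self.fusion_hidden,
            dropout=self.dropout,
            scales=self.scales if scales is None else scales,
            seed=seed,
        )


def desk_config(manifest: str, workdir: str, seed: int = 0, **overrides) -> RunConfig:
    """Desk-scale profile: tiny backbone, 500 iterations, CPU-sized runs."""
    return RunConfig(
        manifest=manifest, workdir=workdir, seed=seed,
        train=TrainConfig(iterations=500, seed=seed), **overrides,
    )


def reference_config(manifest: str, workdir: str, seed: int = 0, **overrides) -> RunConfig:
    """Reference-scale profile: 24-block foundation backbone (externally
    supplied weights), 20 000 iterations per fold, 60% freezing."""
    return RunConfig(
        manifest=manifest, workdir=workdir, seed=seed, backbone="uni-adapter",
        train=TrainConfig(iterations=20000, seed=seed), **overrides,
    )


PROFILES = {"desk": desk_config, "reference": reference_config}


@dataclass
class FeatureTable:
    """Featurized patch triples: provenance rows + per-scale feature matrices."""

    index: pd.DataFrame  # columns: slide_id, x0, y0, ps_block_index
    feats: dict[str, np.ndarray]  # scale -> (N, 576)
    scan_stats: list[TileScanStats] = field(default_factory=list)
    n_ps_discarded: int = 0


def extract_features(
    records: list[SlideRecord],
    filter_config: FilterConfig = FilterConfig(),
    hierarchy_config: HierarchyConfig = HierarchyConfig(),
) -> FeatureTable:
    """Tile every slide, build patch triples, and featurize them.

    Slides are processed one at a time (a slide's pixels never outlive its
    own extraction), so memory stays flat in cohort size.
    """
    rows = []
    feats: dict[str, list[np.ndarray]] = {"l": [], "m": [], "s": []}
    all_stats: list[TileScanStats] = []
    n_discarded = 0
    for slide in records:
        image = load_slide_image(slide.image_path)
        mask = load_mask(slide.mask_path)
        stats = TileScanStats(slide.slide_id)
        for candidate, pixels in _scan_arrays(slide, image, mask, filter_config, stats):
            triple = build_triple(candidate, pixels, hierarchy_config)
            if triple is None:
                n_discarded += 1
                continue
            rows.append(
                {
                    "slide_id": triple.slide_id,
                    "x0": triple.x0,
                    "y0": triple.y0,
                    "ps_block_index": triple.ps_block_index,
                }
            )
            feats["l"].append(featurize(triple.p_l))
            feats["m"].append(featurize(triple.p_m))
            feats["s"].append(featurize(triple.p_s))
        all_stats.append(stats)
        logger.info(
            "slide %s: %d windows, %d bg-rejected, %d tumor-rejected, %d accepted",
            slide.slide_id, stats.n_windows, stats.n_background_rejected,
            stats.n_tumor_rejected, stats.n_accepted,
        )
    index = pd.DataFrame(rows, columns=["slide_id", "x0", "y0", "ps_block_index"])
    matrices = {
        s: (np.stack(v) if v else np.empty((0, 576), dtype=np.float32))
        for s, v in feats.items()
    }
    return FeatureTable(index=index, feats=matrices, scan_stats=all_stats, n_ps_discarded=n_discarded)


def run_cv(
    table: FeatureTable,
    manifest: pd.DataFrame,
    config: RunConfig,
    scales: tuple[str, ...] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Patient-grouped k-fold cross-validation of the hierarchical model.

    Class balancing is applied to the training fold only; test slides are
    scored on all their patches. Returns (metrics report, predictions frame).
    """
    scales = config.scales if scales is None else scales
    labeled = table.index.copy()
    labeled["row"] = np.arange(len(labeled))
    labeled = inherit_labels(labeled, manifest)
    if labeled.empty:
        raise ValueError("no labeled patches: cannot run cross-validation")

    folds = kfold_split(manifest, k=config.k, seed=stage_seed(config.seed, "split"))
    slide_labels = dict(zip(manifest["slide_id"], manifest["subtype"]))

    predictions: list[dict] = []
    fold_class_auc: dict[str, list[float]] = {c: [] for c in SUBTYPES}
    fold_macro: list[float] = []
    fold_curves: dict[str, list] = {c: [] for c in SUBTYPES}

    for fold in folds:
        fold_preds = _run_fold(table, labeled, fold, manifest, config, scales)
        y_true = np.array([slide_labels[p.slide_id] for p in fold_preds])
        per_class = []
        for j, cls in enumerate(SUBTYPES):
            scores = np.array([p.probs[j] for p in fold_preds])
            binary = y_true == cls
            if binary.all() or not binary.any():
                warnings.warn(f"fold {fold.fold_index}: class {cls} absent on one side; AUROC skipped")
                auc = float("nan")
            else:
                auc = roc_auc(scores, binary)
                fold_curves[cls].append(roc_curve_points(scores, binary))
            fold_class_auc[cls].append(auc)
            per_class.append(auc)
        finite = [v for v in per_class if np.isfinite(v)]
        if len(finite) < len(SUBTYPES):
            warnings.warn(
                f"fold {fold.fold_index}: macro AUROC averages the {len(finite)} "
                "classes with defined AUROC"
            )
        if finite:
            fold_macro.append(float(np.mean(finite)))
        for p in fold_preds:
            predictions.append(
                {
                    "slide_id": p.slide_id,
                    **{f"p_{c}": p.probs[j] for j, c in enumerate(SUBTYPES)},
                    "n_patches": p.n_patches,
                    "label": slide_labels[p.slide_id],
                    "fold": fold.fold_index,
                }
            )

    preds_df = pd.DataFrame(predictions)
    pooled_preds = [
        SlidePrediction(r.slide_id, np.array([getattr(r, f"p_{c}") for c in SUBTYPES]), r.n_patches)
        for r in preds_df.itertuples(index=False)
    ]
    pooled_true = preds_df["label"].to_numpy()
    pooled_class_auc = {}
    for j, cls in enumerate(SUBTYPES):
        binary = pooled_true == cls
        pooled_class_auc[cls] = roc_auc(preds_df[f"p_{cls}"].to_numpy(), binary)

    def _ci(values: list[float]) -> tuple[float, float, float]:
        finite = [v for v in values if np.isfinite(v)]
        if len(finite) >= 2:
            return fold_ci(finite, config.ci_method)
        if len(finite) == 1:
            return finite[0], float("nan"), float("nan")
        return float("nan"), float("nan"), float("nan")

    report = {
        "per_class_auroc": {
            cls: dict(
                zip(("mean", "ci_low", "ci_high"), _ci(fold_class_auc[cls])),
                per_fold=fold_class_auc[cls],
            )
            for cls in SUBTYPES
        },
        "macro_auroc": dict(
            zip(("mean", "ci_low", "ci_high"), _ci(fold_macro)),
            per_fold=fold_macro,
        ),
        "pooled_auroc": {**pooled_class_auc, "macro": macro_auroc(list(pooled_class_auc.values()))},
        "threshold_metrics": classification_metrics(
            pooled_preds, {r.slide_id: r.label for r in preds_df.itertuples(index=False)}
        ),
        "roc_curves": {
            cls: {
                "fpr": interp_roc(fold_curves[cls])[0].tolist(),
                "mean_tpr": interp_roc(fold_curves[cls])[1].tolist(),
            }
            for cls in SUBTYPES
            if fold_curves[cls]
        },
        "scales": list(scales),
        "k": config.k,
        "seed": config.seed,
    }
    return report, preds_df


def _run_fold(
    table: FeatureTable,
    labeled: pd.DataFrame,
    fold: FoldSplit,
    manifest: pd.DataFrame,
    config: RunConfig,
    scales: tuple[str, ...],
) -> list[SlidePrediction]:
    train_rows = labeled[labeled["slide_id"].isin(fold.train_slide_ids)]
    balanced = balance_patches(
        train_rows,
        config.train.balance_rates,
        seed=stage_seed(config.seed, f"balance-fold{fold.fold_index}"),
    )
    rows = balanced["row"].to_numpy()
    feats = {s: table.feats[s][rows] for s in scales}
    labels = balanced["subtype"].map(CLASS_INDEX).to_numpy()

    model = HiModel(config.model_config(stage_seed(config.seed, f"model-fold{fold.fold_index}"), scales))
    train_cfg = dataclasses.replace(
        config.train, seed=stage_seed(config.seed, f"train-fold{fold.fold_index}")
    )
    model, _ = train(model, feats, labels, train_cfg)

    preds = []
    for sid in fold.test_slide_ids:
        srows = labeled.loc[labeled["slide_id"] == sid, "row"].to_numpy()
        if len(srows) == 0:
            warnings.warn(f"slide {sid}: no patches survived extraction; skipped in evaluation")
            continue
        logits = model.predict_logits({s: table.feats[s][srows] for s in scales})
        preds.append(aggregate_slide(logits, sid))
    return preds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts under ``workdir``.

    Writes ``tile_index.csv``, ``predictions.csv`` and ``metrics.json``
    (stamped with the config hash and seed). Returns the metrics report.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    try:
        records = read_manifest(config.manifest)
    except Exception as exc:
        raise RuntimeError(f"[manifest] {exc}") from exc
    manifest_df = pd.DataFrame(
        [
            {"slide_id": r.slide_id, "patient_id": r.patient_id, "subtype": r.subtype}
            for r in records
        ]
    )

    try:
        table = extract_features(records, config.filter, config.hierarchy)
    except Exception as exc:
        raise RuntimeError(f"[tile] {exc}") from exc
    index_out = table.index.copy()
    index_out["config_hash"] = chash
    index_out.to_csv(workdir / "tile_index.csv", index=False)

    try:
        report, preds = run_cv(table, manifest_df, config)
    except Exception as exc:
        raise RuntimeError(f"[cv] {exc}") from exc

    preds.insert(0, "config_hash", chash)
    preds.to_csv(workdir / "predictions.csv", index=False)
    report_out = {"config_hash": chash, "seed": config.seed, "config": config.to_dict(), **report}
    with open(workdir / "metrics.json", "w") as fh:
        json.dump(report_out, fh, indent=2)
    return report_out


def assert_config_hash(found: str, expected: str, override: bool = False) -> None:
    """Refuse to consume an artifact from a different configuration."""
    if found != expected and not override:
        raise ValueError(
            f"artifact config hash {found} does not match the current configuration "
            f"{expected}; pass override to consume it anyway"
        )
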