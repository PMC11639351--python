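"""Patch-based training loop, fine-tuning, and Dice evaluation.

Training follows the crop-based regime: per epoch each training case yields
one patch — alternating 1:1 between purely random and label-guided crops to
fight the tumour/background class imbalance — which is augmented and
optimised against the soft-dice + cross-entropy loss with AdamW under a
cosine-annealed learning rate (initial 1e-4, batch size 1). The best
checkpoint by validation whole-tumour Dice is kept. Fine-tuning re-uses the
encoder ("deep layers") of a checkpoint and re-initialises the input stem
and segmentation head when channel counts differ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import AugmentConfig, ModelConfig, TrainConfig
from .data import (LabelMap, Volume, augment, label_guided_crop, load_labels,
                   load_volume, random_crop)
from .errors import ValidationError
from .inference import sliding_window_infer
from .losses import dice_score, one_hot, regions_from_labels, soft_dice_ce_loss
from .model import TCTNet, load_checkpoint, save_checkpoint
from .nn import AdamW, clip_grad_norm, cosine_lr

__all__ = [
    "Case",
    "load_dataset",
    "split_cases",
    "TrainResult",
    "kfold_splits",
    "run_training",
    "run_finetune",
    "evaluate",
    "predict_case",
]


@dataclass
class Case:
    name: str
    volume: Volume
    labels: LabelMap


@dataclass
class TrainResult:
    checkpoint_path: Path | None
    history: list[dict] = field(default_factory=list)
    best_val_dice: float = float("nan")
    model: TCTNet | None = None


def load_dataset(data_dir: str | Path) -> list[Case]:
    """Load all cases listed in a dataset manifest (see `generate_dataset`)."""
    data_dir = Path(data_dir)
    manifest_path = data_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    manifest = json.loads(manifest_path.read_text())
    cases = []
    for entry in manifest["cases"]:
        vol = load_volume(data_dir / entry["image"])
        lab = load_labels(data_dir / entry["label"], vol.spatial_shape)
        cases.append(Case(entry["name"], vol, lab))
    if not cases:
        raise ValidationError(f"dataset at {data_dir} is empty")
    return cases


def split_cases(cases: list[Case], val_fraction: float, seed: int
                ) -> tuple[list[Case], list[Case]]:
    """Reproducible 80/20-style split by case."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    n_val = int(round(val_fraction * len(cases)))
    if len(cases) > 1:
        n_val = min(max(n_val, 1), len(cases) - 1)
    else:
        n_val = 0
    val_idx = set(order[:n_val].tolist())
    train = [c for i, c in enumerate(cases) if i not in val_idx]
    val = [c for i, c in enumerate(cases) if i in val_idx]
    return train, val


def kfold_splits(cases: list[Case], k: int = 5, seed: int = 0
                 ) -> list[tuple[list[Case], list[Case]]]:
    """Seeded k-fold cross-validation splits by case (train, held-out) pairs."""
    if k < 2 or k > len(cases):
        raise ValidationError(f"k must be in [2, {len(cases)}], got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cases))
    folds = np.array_split(order, k)
    splits = []
    for fold in folds:
        held = set(fold.tolist())
        splits.append((
            [c for i, c in enumerate(cases) if i not in held],
            [c for i, c in enumerate(cases) if i in held],
        ))
    return splits


def _sample_patch(case: Case, size, guided: bool, rng) -> tuple[np.ndarray, np.ndarray]:
    if guided and (case.labels.labels > 0).any():
        pair = label_guided_crop(case.volume, case.labels, size, rng)
    else:
        pair = random_crop(case.volume, case.labels, size, rng)
    return pair


def validation_dice(model: TCTNet, cases: list[Case], roi, region: str = "WT"
                    ) -> float:
    if not cases:
        return float("nan")
    scores = []
    for case in cases:
        probs = sliding_window_infer(case.volume, model.predict, roi,
                                     overlap=0.5, use_gaussian=True)
        pred = prediction_to_labels(probs)
        scores.append(dice_score(regions_from_labels(pred)[region],
                                 regions_from_labels(case.labels.labels)[region]))
    return float(np.mean(scores))


CLASS_VALUES = (0, 1, 2, 4)


def prediction_to_labels(probs: np.ndarray,
                         class_values: tuple[int, ...] = CLASS_VALUES) -> np.ndarray:
    """Argmax the class axis back to BraTS label values."""
    idx = np.argmax(probs, axis=0)
    return np.asarray(class_values, dtype=np.int16)[idx]


def run_training(train_cfg: TrainConfig, model_cfg: ModelConfig,
                 data_dir: str | Path | None = None,
                 cases: list[Case] | None = None,
                 augment_cfg: AugmentConfig | None = None,
                 model: TCTNet | None = None) -> TrainResult:
    """Train a model on a phantom/NIfTI dataset; returns history + best model."""
    if cases is None:
        if data_dir is None:
            raise ValidationError("provide either data_dir or cases")
        cases = load_dataset(data_dir)
    train_cases, val_cases = split_cases(cases, train_cfg.val_fraction, train_cfg.seed)
    if not train_cases:
        raise ValidationError("no training cases after the validation split")

    model = model if model is not None else TCTNet(model_cfg)
    params = model.parameters()
    opt = AdamW(params, lr=train_cfg.lr, weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed)
    augment_cfg = augment_cfg if augment_cfg is not None else AugmentConfig()
    size = train_cfg.patch_size

    history: list[dict] = []
    best_dice = -1.0
    best_state = None
    metrics_file = (open(train_cfg.metrics_path, "a")
                    if train_cfg.metrics_path else None)
    step = 0
    try:
        for epoch in range(train_cfg.epochs):
            lr = (cosine_lr(train_cfg.lr, epoch, train_cfg.epochs)
                  if train_cfg.schedule == "cosine" else train_cfg.lr)
            opt.lr = lr
            epoch_losses = []
            for case in train_cases:
                guided = rng.random() < train_cfg.crop_mix
                pair = _sample_patch(case, size, guided, rng)
                pair = augment(pair, rng, augment_cfg)
                target = one_hot(pair.labels, CLASS_VALUES, dtype=model.cfg.np_dtype)
                probs = model(pair.image.astype(model.cfg.np_dtype))
                loss = soft_dice_ce_loss(probs, target)
                loss_val = loss.item()
                if not math.isfinite(loss_val):
                    raise RuntimeError(
                        f"non-finite loss ({loss_val}) at epoch {epoch}, "
                        f"case {case.name}; aborting"
                    )
                model.zero_grad()
                loss.backward()
                clip_grad_norm(params, train_cfg.grad_clip)
                opt.step()
                epoch_losses.append(loss_val)
                step += 1
            record = {"epoch": epoch, "lr": lr,
                      "loss": float(np.mean(epoch_losses)), "step": step}
            if val_cases and (epoch % train_cfg.val_every == 0
                              or epoch == train_cfg.epochs - 1):
                record["val_wt_dice"] = validation_dice(model, val_cases, size)
                if record["val_wt_dice"] >= best_dice:
                    best_dice = record["val_wt_dice"]
                    best_state = model.state_dict()
            history.append(record)
            if metrics_file:
                metrics_file.write(json.dumps(record) + "\n")
                metrics_file.flush()
    finally:
        if metrics_file:
            metrics_file.close()

    if best_state is not None:
        model.load_state_dict(best_state)
    ckpt_path = None
    if train_cfg.checkpoint_path:
        ckpt_path = Path(train_cfg.checkpoint_path)
        save_checkpoint(ckpt_path, model,
                        extra={"best_val_dice": best_dice, "epochs": train_cfg.epochs})
    return TrainResult(ckpt_path, history,
                       best_dice if best_state is not None else float("nan"), model)


def warm_start_from(checkpoint: str | Path, model_cfg: ModelConfig
                    ) -> tuple[TCTNet, list[str]]:
    """Build a model for `model_cfg` initialised from a checkpoint's weights.

    All encoder stages ("deep layers") must match in width; the input stem
    and the segmentation head are freshly initialised whenever the channel
    counts differ. Returns the model and the names of re-initialised
    parameters.
    """
    src_model, _ = load_checkpoint(checkpoint)
    if src_model.cfg.encoder.stage_widths != model_cfg.encoder.stage_widths:
        raise ValidationError(
            f"incompatible encoder widths: checkpoint "
            f"{src_model.cfg.encoder.stage_widths} vs requested "
            f"{model_cfg.encoder.stage_widths}"
        )
    model = TCTNet(model_cfg)
    skipped = model.load_state_dict(src_model.state_dict(), strict=False)
    return model, skipped


def run_finetune(checkpoint: str | Path, train_cfg: TrainConfig,
                 model_cfg: ModelConfig, data_dir: str | Path | None = None,
                 cases: list[Case] | None = None,
                 augment_cfg: AugmentConfig | None = None) -> TrainResult:
    """Fine-tune the whole network from a checkpoint on a new dataset."""
    model, _ = warm_start_from(checkpoint, model_cfg)
    return run_training(train_cfg, model_cfg, data_dir=data_dir, cases=cases,
                        augment_cfg=augment_cfg, model=model)


def evaluate(pred_dir: str | Path, gt_dir: str | Path) -> dict:
    """Per-case and mean/sd WT/TC/ET Dice between prediction and truth dirs.

    Both directories must hold label NIfTIs named `<case>_label.nii.gz` (or
    any identical basenames); case lists must match exactly.
    """
    pred_dir, gt_dir = Path(pred_dir), Path(gt_dir)

    def case_map(d: Path) -> dict[str, Path]:
        files = sorted(list(d.glob("*.nii")) + list(d.glob("*.nii.gz")))
        return {f.name.replace(".nii.gz", "").replace(".nii", ""): f for f in files}

    preds, gts = case_map(pred_dir), case_map(gt_dir)
    if set(preds) != set(gts):
        raise ValidationError(
            f"case mismatch: only-in-predictions {sorted(set(preds) - set(gts))}, "
            f"only-in-ground-truth {sorted(set(gts) - set(preds))}"
        )
    per_case = {}
    for name in sorted(preds):
        p = regions_from_labels(load_labels(preds[name]).labels)
        g = regions_from_labels(load_labels(gts[name]).labels)
        per_case[name] = {r: dice_score(p[r], g[r]) for r in ("WT", "TC", "ET")}
    report = {"per_case": per_case, "mean": {}, "sd": {}}
    for r in ("WT", "TC", "ET"):
        vals = [per_case[n][r] for n in per_case]
        report["mean"][r] = float(np.mean(vals))
        report["sd"][r] = float(np.std(vals))
    return report


def predict_case(model: TCTNet, vol: Volume, roi, overlap: float = 0.5,
                 use_gaussian: bool = True) -> np.ndarray:
    """Sliding-window inference followed by argmax to BraTS label values."""
    probs = sliding_window_infer(vol, model.predict, roi, overlap, use_gaussian)
    return prediction_to_labels(probs)
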