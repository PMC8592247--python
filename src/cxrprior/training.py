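"""The three-phase sequential training protocol and its ablations.

Phase 1 trains the dual-stream model for gender detection on the
NMF+CLAHE version of the data, phase 2 continues with age detection on
the same version, and phase 3 retrains for thorax-disease detection on
the augmented originals — each later phase inheriting the previous
phase's stream backbones while the classification head is swapped.
The nine named variants (GD_NMF, GD_NMF => AD_NMF => DD_ORG, DD_ORG,
...) encode which chain of task/dataset-version pairs is executed, so
single-task baselines and partial-transfer ablations share one code
path.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from cxrprior.losses import (
    MarginLossParams,
    inverse_frequency_weights,
    margin_loss_with_grad,
)
from cxrprior.metrics import macro_auc
from cxrprior.model import DualStreamModel, ModelConfig
from cxrprior.nn import Adam
from cxrprior.phantom import AGE_BINS, DISEASE_CLASSES, GENDERS, ImageRecord
from cxrprior.preprocess import DatasetVersion

Task = Literal["gender", "age", "disease"]

#: The nine protocol variants; keys are the canonical names.
VARIANTS: tuple[str, ...] = (
    "GD_NMF",
    "GD_NMF => AD_NMF",
    "GD_NMF => AD_NMF => DD_ORG",
    "AD_NMF",
    "GD_NMF => DD_ORG",
    "AD_NMF => DD_ORG",
    "GD_ORG",
    "AD_ORG",
    "DD_ORG",
)

_TOKEN = {
    "GD": "gender",
    "AD": "age",
    "DD": "disease",
}
_VERSION = {"NMF": "Ver_NMF", "ORG": "Ver_ORG"}


def task_classes(task: Task) -> tuple[str, ...]:
    if task == "gender":
        return GENDERS
    if task == "age":
        return AGE_BINS
    if task == "disease":
        return DISEASE_CLASSES
    raise ValueError(f"unknown task {task!r}")


def task_kind(task: Task) -> str:
    return "multi" if task == "disease" else "single"


def encode_targets(records: Sequence[ImageRecord], task: Task,
                   classes: Sequence[str] | None = None) -> np.ndarray:
    """Binary target matrix (N, n_classes) for a task view."""
    classes = tuple(classes) if classes is not None else task_classes(task)
    t = np.zeros((len(records), len(classes)), dtype=np.float64)
    for i, rec in enumerate(records):
        if task == "gender":
            t[i, classes.index(rec.gender)] = 1.0
        elif task == "age":
            t[i, classes.index(rec.age_bin)] = 1.0
        else:
            for d in rec.diseases:
                if d in classes:
                    t[i, classes.index(d)] = 1.0
    return t


def image_matrix(records: Sequence[ImageRecord]) -> np.ndarray:
    """Stack records' pixels as a (N, H, W) float array in [0, 1]."""
    return np.stack([r.pixels for r in records]).astype(np.float32) / 255.0


@dataclass(frozen=True)
class PhaseConfig:
    """One training phase: a task on a dataset version.

    Defaults follow the protocol: gender/age train with Adam at lr
    0.001 for 10 epochs, disease at lr 0.0001 for 100 epochs; the
    ``fast`` profile (2/2/5 epochs) keeps desk-scale experiments and
    the test suite inside minutes.
    """

    task: Task
    dataset_version: Literal["Ver_ORG", "Ver_NMF"]
    learning_rate: float = 0.001
    epochs: int = 10
    optimizer: str = "adam"
    batch_size: int = 32
    class_weighting: bool = False
    loss_params: MarginLossParams = MarginLossParams()
    disease_classes: tuple[str, ...] | None = None

    @property
    def classes(self) -> tuple[str, ...]:
        if self.task == "disease" and self.disease_classes is not None:
            return self.disease_classes
        return task_classes(self.task)


def default_phase(task: Task, version: str, fast: bool = False,
                  **overrides) -> PhaseConfig:
    if task == "disease":
        base = dict(learning_rate=0.0001, epochs=5 if fast else 100)
    else:
        base = dict(learning_rate=0.001, epochs=2 if fast else 10)
    base.update(overrides)
    return PhaseConfig(task=task, dataset_version=version, **base)


@dataclass
class PhaseResult:
    config: PhaseConfig
    log: pd.DataFrame                  # one row per epoch
    best_epoch: int | None
    best_metric: float | None
    checkpoint_path: Path | None
    trained_ids: list[str]             # every id that appeared in a training batch


@dataclass
class ProtocolRun:
    variant: str
    seed: int
    phases: list[PhaseResult] = dc_field(default_factory=list)
    model: DualStreamModel | None = None


class VariantError(ValueError):
    pass


def parse_variant(variant: str) -> list[tuple[Task, str]]:
    """Split a Table-style variant name into (task, version) phases."""
    name = re.sub(r"\s+", " ", variant.replace("⇒", "=>")).strip()
    canonical = {re.sub(r"\s+", "", v): v for v in VARIANTS}
    if re.sub(r"\s+", "", name) not in canonical:
        raise VariantError(
            f"unknown variant {variant!r}; valid names: {list(VARIANTS)}"
        )
    phases = []
    for token in name.split("=>"):
        code, ver = token.strip().split("_")
        phases.append((_TOKEN[code], _VERSION[ver]))
    return phases


def _snapshot(model: DualStreamModel) -> dict[str, np.ndarray]:
    return {k: v.copy() for k, v in model._state_arrays().items()}


def _restore(model: DualStreamModel, state: dict[str, np.ndarray]) -> None:
    for k, v in model._state_arrays().items():
        v[...] = state[k]


def run_phase(
    cfg: PhaseConfig,
    data: DatasetVersion,
    model: DualStreamModel,
    seed: int = 0,
    checkpoint_path: str | Path | None = None,
) -> PhaseResult:
    """Train one phase; the model ends holding the best-validation weights.

    The per-epoch log records train/val loss and accuracy (plus val
    macro-AUC for the multi-label disease task).  With ``epochs=0`` the
    model is left at its initialization and the log is empty.
    """
    if data.tag != cfg.dataset_version:
        raise ValueError(
            f"dataset tag {data.tag} does not match the phase's "
            f"{cfg.dataset_version} (variant naming: GD/AD/DD _ NMF/ORG)"
        )
    if model.cfg.n_classes != len(cfg.classes):
        raise ValueError(
            f"model head has {model.cfg.n_classes} classes but task "
            f"{cfg.task!r} needs {len(cfg.classes)}; apply swap_head first"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7261696E]))
    train_recs = data.subset("train")
    val_recs = data.subset("val")
    x_train = image_matrix(train_recs) if train_recs else np.empty((0,))
    t_train = encode_targets(train_recs, cfg.task, cfg.classes)
    x_val = image_matrix(val_recs) if val_recs else None
    t_val = encode_targets(val_recs, cfg.task, cfg.classes) if val_recs else None

    weights = (
        inverse_frequency_weights(t_train)
        if cfg.class_weighting and len(train_recs)
        else None
    )
    opt = Adam(model.params(), lr=cfg.learning_rate)
    is_multi = task_kind(cfg.task) == "multi"
    best_metric, best_epoch, best_state = None, None, None
    rows = []
    trained_ids: list[str] = []

    for epoch in range(cfg.epochs):
        order = rng.permutation(len(train_recs))
        losses = []
        batch_scores, batch_targets = [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            trained_ids.extend(train_recs[i].image_id for i in idx)
            emb, _ = model.forward(x_train[idx], train=True)
            loss, dloss_ds = margin_loss_with_grad(
                emb.scores, t_train[idx], cfg.loss_params, weights
            )
            safe = np.maximum(emb.scores, 1e-12)[..., None]
            grad_vec = (dloss_ds[..., None] / safe) * emb.vectors
            opt.zero_grad()
            model.backward(grad_vec.astype(emb.vectors.dtype))
            opt.step()
            losses.append(loss)
            batch_scores.append(emb.scores)
            batch_targets.append(t_train[idx])

        # Train metrics come from the training batches themselves (the
        # usual running-metric convention), so no extra pass is needed.
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)) if losses else np.nan}
        if batch_scores:
            row["train_acc"] = _accuracy(
                model, np.concatenate(batch_scores), np.concatenate(batch_targets),
                is_multi,
            )
        else:
            row["train_acc"] = np.nan
        if val_recs:
            val_scores = _scores_in_batches(model, x_val, cfg.batch_size)
            vloss, _ = margin_loss_with_grad(val_scores, t_val, cfg.loss_params)
            row["val_loss"] = vloss
            row["val_acc"] = _accuracy(model, val_scores, t_val, is_multi)
            if is_multi:
                try:
                    row["val_macro_auc"] = macro_auc(val_scores, t_val)
                except ValueError:
                    row["val_macro_auc"] = np.nan
            metric = row.get("val_macro_auc") if is_multi else row["val_acc"]
            if metric is not None and not np.isnan(metric):
                if best_metric is None or metric > best_metric:
                    best_metric, best_epoch = float(metric), epoch
                    best_state = _snapshot(model)
        rows.append(row)

    if best_state is not None:
        _restore(model, best_state)

    path = None
    if checkpoint_path is not None:
        path = model.save(checkpoint_path)
    log = pd.DataFrame(rows)
    return PhaseResult(
        config=cfg,
        log=log,
        best_epoch=best_epoch,
        best_metric=best_metric,
        checkpoint_path=path,
        trained_ids=trained_ids,
    )


def _scores_in_batches(model: DualStreamModel, x: np.ndarray,
                       batch_size: int) -> np.ndarray:
    parts = [
        model.forward(x[i : i + batch_size], train=False)[0].scores
        for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(parts) if parts else np.empty((0, model.cfg.n_classes))


def _accuracy(model: DualStreamModel, scores: np.ndarray, targets: np.ndarray,
              is_multi: bool) -> float:
    if len(scores) == 0:
        return np.nan
    if is_multi:
        pred = scores > 0.5
        return float((pred == targets.astype(bool)).mean())
    return float((scores.argmax(axis=1) == targets.argmax(axis=1)).mean())


def run_protocol(
    variant: str,
    versions: dict[str, DatasetVersion],
    seed: int = 0,
    model_cfg: ModelConfig | None = None,
    fast: bool = False,
    out_dir: str | Path | None = None,
    phase_overrides: dict | None = None,
    disease_classes: tuple[str, ...] | None = None,
) -> ProtocolRun:
    """Execute the chain of phases a variant name encodes.

    ``versions`` maps ``Ver_ORG``/``Ver_NMF`` to their datasets (built
    once, sharing ids, labels and roles).  Phase k+1's stream
    backbones are initialized from phase k's best checkpoint; only the
    head is reinitialized for the new task.  ``phase_overrides`` maps a
    task name to :class:`PhaseConfig` field overrides for that task's
    phase (e.g. ``{"disease": {"epochs": 12}}``).
    """
    chain = parse_variant(variant)
    missing = {ver for _, ver in chain} - set(versions)
    if missing:
        raise VariantError(f"variant {variant!r} needs dataset versions {sorted(missing)}")
    first_task = chain[0][0]
    if model_cfg is None:
        some = next(iter(versions.values()))
        model_cfg = ModelConfig(input_size=some.records[0].pixels.shape[0])
    import dataclasses as _dc

    n0 = len(disease_classes) if (first_task == "disease" and disease_classes) \
        else len(task_classes(first_task))
    model = DualStreamModel(
        _dc.replace(model_cfg, n_classes=n0, task_kind=task_kind(first_task)),
        seed=seed,
    )
    run = ProtocolRun(variant=variant, seed=seed)
    out_dir = Path(out_dir) if out_dir is not None else None
    for k, (task, ver) in enumerate(chain):
        if k > 0:
            n_k = len(disease_classes) if (task == "disease" and disease_classes) \
                else len(task_classes(task))
            model.swap_head(n_k, task_kind=task_kind(task), seed=seed + 1000 + k)
        cfg = default_phase(task, ver, fast=fast,
                            **((phase_overrides or {}).get(task, {})))
        if task == "disease" and disease_classes:
            cfg = _dc.replace(cfg, disease_classes=tuple(disease_classes))
        ckpt = (out_dir / f"phase{k + 1}_{task}.npz") if out_dir else None
        run.phases.append(
            run_phase(cfg, versions[ver], model, seed=seed + k, checkpoint_path=ckpt)
        )
    run.model = model
    return run


def evaluate_split(
    model: DualStreamModel,
    data: DatasetVersion,
    task: Task,
    role: str = "test",
    classes: Sequence[str] | None = None,
    batch_size: int = 32,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores and targets for one split, for the metrics module."""
    recs = data.subset(role)
    if not recs:
        raise ValueError(f"no records with role {role!r}")
    x = image_matrix(recs)
    scores = _scores_in_batches(model, x, batch_size)
    targets = encode_targets(recs, task, classes)
    return scores, targets
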