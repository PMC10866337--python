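"""Training, transfer learning, ensembling, and evaluation.

The loss is the mean squared error summed over the two normalized targets.
Training runs to ``max_epochs`` with Adam under a Noam-style warmup/decay
schedule; the validation set selects the best epoch (pure best-epoch
selection — no halting), and the returned bundle carries the parameter
snapshot from that epoch.  Transfer learning initializes every weight from a
pre-trained bundle and keeps its target normalization, then trains for a
small number of epochs (default 10 against 80 for pre-training) so the
broad pre-trained knowledge is refined, not overwritten.

Ensembles are built per fold from different random initializations; member
(fold f, seed i) derives its seed deterministically from (config.seed, f, i),
so 5 folds x 5 members reproduce the same 25 models on every run.
"""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .curation import SplitAssignment
from .errors import ShapeError, UsageError
from .network import (
    FeaturizedRecord,
    ModelBundle,
    backward_records,
    ensemble_predict,
    featurize_records,
    forward_records,
    new_bundle,
)
from .nn import Adam, make_lr_schedule
from .pairtable import PairRecord
from .thermo import ThermoContext, kcal_per_log10

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "train",
    "build_ensemble",
    "member_seed",
    "evaluate",
    "evaluate_folds",
    "finetune_epoch_sweep",
]


@dataclass
class TrainConfig:
    """Training schedule and architecture knobs.

    Defaults follow the framework conventions the architecture derives from:
    hidden width 300, depth 3, a 2x300 ReLU feed-forward head with dropout
    0.05, Adam with linear warmup to 1e-3 then exponential decay, maximum 80
    epochs for pre-training (use 10 for fine-tuning), ensembles of 5.
    """

    max_epochs: int = 80
    batch_size: int = 50
    init_lr: float = 1e-4
    max_lr: float = 1e-3
    final_lr: float = 1e-4
    warmup_epochs: float = 2.0
    hidden: int = 300
    depth: int = 3
    ffn_hidden: Tuple[int, ...] = (300, 300)
    dropout: float = 0.05
    rxn_readout: str = "mean"
    solvent_readout: str = "mean"
    ensemble_size: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 1:
            raise UsageError("max_epochs must be >= 1")
        if self.batch_size < 1:
            raise UsageError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses and validation metrics; best epoch = argmin val loss."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    val_mae: List[np.ndarray] = field(default_factory=list)  # (2,) per epoch
    val_rmse: List[np.ndarray] = field(default_factory=list)

    @property
    def best_epoch(self) -> int:
        return int(np.argmin(self.val_loss))


def member_seed(base: int, fold: int, member: int) -> int:
    """Deterministic sub-seed for ensemble member (fold, member), < 2^31."""
    digest = hashlib.sha256(f"{base}:{fold}:{member}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _predict_norm(
    feats: Sequence[FeaturizedRecord], bundle: ModelBundle, chunk: int = 512
) -> np.ndarray:
    parts = [
        forward_records(feats[i:i + chunk], bundle)
        for i in range(0, len(feats), chunk)
    ]
    return np.concatenate(parts, axis=0)


def train(
    records: Sequence[PairRecord],
    split: SplitAssignment,
    config: TrainConfig,
    init: Optional[ModelBundle] = None,
    cache: Optional[Dict] = None,
) -> Tuple[ModelBundle, TrainHistory]:
    """Train one model; returns the best-validation-epoch snapshot.

    With ``init`` given, every weight starts from the pre-trained bundle and
    the stored target normalization is kept, so fine-tuning refines the same
    function; shapes must match (ShapeError otherwise).
    """
    if split.n_records != len(records):
        raise UsageError("split assignment does not cover the record set")
    train_idx = split.indices("train")
    val_idx = split.indices("val")
    if train_idx.size == 0 or val_idx.size == 0:
        raise UsageError("empty train or validation set")

    extras_dim = records[0].extras_width if records else 0
    if init is not None:
        bundle = init.copy()
        if bundle.extras_dim != extras_dim:
            raise ShapeError(
                f"init bundle expects extras width {bundle.extras_dim}, "
                f"data provides {extras_dim}"
            )
    else:
        bundle = new_bundle(
            hidden=config.hidden,
            depth=config.depth,
            ffn_hidden=config.ffn_hidden,
            extras_dim=extras_dim,
            rxn_readout=config.rxn_readout,
            solvent_readout=config.solvent_readout,
            seed=config.seed,
        )
        # target standardization from the training split only
        y_train = np.stack([records[i].targets for i in train_idx])
        bundle.target_mean = y_train.mean(axis=0)
        bundle.target_std = np.maximum(y_train.std(axis=0), 1e-8)

    feats = featurize_records(records, bundle.schema, cache)
    y_norm = bundle.normalize(np.stack([r.targets for r in records]))

    params = bundle.param_arrays()
    optimizer = Adam(params)
    steps_per_epoch = max(1, int(np.ceil(train_idx.size / config.batch_size)))
    lr_at = make_lr_schedule(
        steps_per_epoch,
        config.max_epochs,
        config.warmup_epochs,
        config.init_lr,
        config.max_lr,
        config.final_lr,
    )

    history = TrainHistory()
    best_loss = np.inf
    best_params = None
    val_feats = [feats[i] for i in val_idx]
    y_val_norm = y_norm[val_idx]
    y_val = np.stack([records[i].targets for i in val_idx])
    step = 0
    for epoch in range(config.max_epochs):
        rng = np.random.default_rng(member_seed(config.seed, 7919, epoch))
        order = rng.permutation(train_idx)
        epoch_loss = 0.0
        for start in range(0, order.size, config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            batch_feats = [feats[i] for i in batch_idx]
            preds, fwd_cache = forward_records(
                batch_feats, bundle, config.dropout, rng, want_cache=True
            )
            resid = preds - y_norm[batch_idx]
            epoch_loss += float((resid**2).sum())
            d_preds = 2.0 * resid / batch_idx.size
            grads = backward_records(d_preds, fwd_cache, bundle)
            optimizer.step(grads, lr_at(step))
            step += 1
        history.train_loss.append(epoch_loss / order.size)

        val_pred_norm = _predict_norm(val_feats, bundle)
        val_loss = float(((val_pred_norm - y_val_norm) ** 2).sum(axis=1).mean())
        history.val_loss.append(val_loss)
        val_pred = bundle.denormalize(val_pred_norm)
        err = val_pred - y_val
        history.val_mae.append(np.abs(err).mean(axis=0))
        history.val_rmse.append(np.sqrt((err**2).mean(axis=0)))
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}

    if best_params is not None:
        for k, v in bundle.param_arrays().items():
            v[...] = best_params[k]
    return bundle, history


def build_ensemble(
    records: Sequence[PairRecord],
    folds: Sequence[SplitAssignment],
    config: TrainConfig,
    init: Optional[Sequence[ModelBundle]] = None,
    cache: Optional[Dict] = None,
    histories: Optional[List[TrainHistory]] = None,
) -> List[ModelBundle]:
    """folds x ensemble_size bundles; when ``init`` is given it must hold one
    pre-trained bundle per (fold, member) and each fine-tuned model starts
    from its counterpart."""
    if len(folds) < 1:
        raise UsageError("need at least one fold")
    cache = cache if cache is not None else {}
    bundles: List[ModelBundle] = []
    k = 0
    for f, split in enumerate(folds):
        for i in range(config.ensemble_size):
            member_cfg = replace(config, seed=member_seed(config.seed, f, i))
            start = init[k] if init is not None else None
            bundle, hist = train(records, split, member_cfg, init=start, cache=cache)
            bundles.append(bundle)
            if histories is not None:
                histories.append(hist)
            k += 1
    return bundles


def evaluate(
    bundles: Sequence[ModelBundle],
    records: Sequence[PairRecord],
    unit: str = "kcal/mol",
    cache: Optional[Dict] = None,
) -> Dict[str, float]:
    """Per-target MAE and RMSE of the ensemble-mean prediction.

    ``unit="log10"`` converts the free-energy errors to log10 rate-ratio
    units by dividing by R·T·ln 10 at 298 K.
    """
    if len(records) == 0:
        raise UsageError("cannot evaluate on an empty record set")
    mean, _ = ensemble_predict(bundles, records, cache)
    y = np.stack([r.targets for r in records])
    err = mean - y
    scale = 1.0
    if unit == "log10":
        scale = 1.0 / kcal_per_log10(ThermoContext())
    elif unit != "kcal/mol":
        raise UsageError(f"unknown unit {unit!r}")
    mae = np.abs(err).mean(axis=0) * scale
    rmse = np.sqrt((err**2).mean(axis=0)) * scale
    return {
        "ddG_mae": float(mae[0]),
        "ddG_rmse": float(rmse[0]),
        "ddH_mae": float(mae[1]),
        "ddH_rmse": float(rmse[1]),
        "n": len(records),
        "unit": unit,
    }


def evaluate_folds(
    per_fold: Sequence[Tuple[Sequence[ModelBundle], Sequence[PairRecord]]],
    unit: str = "kcal/mol",
    cache: Optional[Dict] = None,
) -> Dict[str, float]:
    """Fold-wise mean +/- sd of the ensemble metrics (sd 0 for one fold)."""
    rows = [evaluate(bundles, recs, unit, cache) for bundles, recs in per_fold]
    out: Dict[str, float] = {"n_folds": len(rows)}
    for key in ("ddG_mae", "ddG_rmse", "ddH_mae", "ddH_rmse"):
        vals = np.array([r[key] for r in rows])
        out[key] = float(vals.mean())
        out[f"{key}_sd"] = float(vals.std(ddof=1)) if len(rows) > 1 else 0.0
    return out


def finetune_epoch_sweep(
    pretrained: ModelBundle,
    finetune_records: Sequence[PairRecord],
    finetune_split: SplitAssignment,
    holdout_records: Sequence[PairRecord],
    epoch_grid: Sequence[int],
    config: TrainConfig,
    cache: Optional[Dict] = None,
) -> List[Dict[str, float]]:
    """Re-run fine-tuning at each maximum-epoch value and report the holdout
    and fine-tune-validation MAE; epoch 0 is the untouched pre-trained model.
    Used to locate the plateau epoch for transfer learning."""
    cache = cache if cache is not None else {}
    val_records = [finetune_records[i] for i in finetune_split.indices("val")]
    rows: List[Dict[str, float]] = []
    for n_epochs in epoch_grid:
        if n_epochs == 0:
            bundle = pretrained
        else:
            bundle, _ = train(
                finetune_records,
                finetune_split,
                replace(config, max_epochs=int(n_epochs)),
                init=pretrained,
                cache=cache,
            )
        hold = evaluate([bundle], holdout_records, cache=cache)
        val = evaluate([bundle], val_records, cache=cache)
        rows.append(
            {
                "max_epochs": float(n_epochs),
                "holdout_ddG_mae": hold["ddG_mae"],
                "holdout_ddH_mae": hold["ddH_mae"],
                "val_ddG_mae": val["ddG_mae"],
                "val_ddH_mae": val["ddH_mae"],
            }
        )
    return rows
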