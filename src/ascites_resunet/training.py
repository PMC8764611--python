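"""Training protocol: Adam + BCE/Dice, stratified k-fold epoch selection.

Cross-validation follows the protocol of selecting the training epoch
rather than early-stopping inside folds: k models are trained for the
full epoch budget, the validation cost curves are averaged across
folds, and the epoch with the lowest mean validation cost wins (ties
go to the smaller epoch).  The final model is then retrained on the
whole training set for exactly that many epochs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, build_model
from .nn import ResUNet, bce_dice_from_probs, loss_and_grad_from_logits
from .nn.optim import Adam


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 50
    bce_weight: float = 1.0
    dice_weight: float = 1.0
    dice_eps: float = 1.0
    k_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning rate, batch size and max_epochs must be positive")
        if self.bce_weight < 0 or self.dice_weight < 0:
            raise ValueError("loss weights must be non-negative")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def bce_dice_loss(
    probabilities: np.ndarray,
    truth: np.ndarray,
    bce_weight: float = 1.0,
    dice_weight: float = 1.0,
    eps: float = 1.0,
) -> float:
    """Combined loss from probability maps (see ``nn.loss`` for the form)."""
    return bce_dice_from_probs(probabilities, truth, bce_weight, dice_weight, eps)


def make_folds(labels: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment in {0..k-1}; per-class sizes differ <= 1."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        small = classes[counts.argmin()]
        raise ValueError(
            f"class {small!r} has {counts.min()} entries, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(labels), dtype=int)
    for fold_id, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        folds[val_idx] = fold_id
    return folds


@dataclass
class TrainingHistory:
    """Per-fold, per-epoch training and validation costs."""

    folds: list[list[dict]] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return min(len(f) for f in self.folds)

    def mean_validation_cost(self) -> np.ndarray:
        e = self.n_epochs
        return np.mean(
            [[rec["val_cost"] for rec in fold[:e]] for fold in self.folds], axis=0
        )


def select_best_epoch(mean_val_costs: np.ndarray) -> int:
    """1-based epoch with the lowest mean validation cost; ties -> smallest."""
    return int(np.argmin(mean_val_costs)) + 1


def train_loop(
    net: ResUNet,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
    epochs: int,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> list[dict]:
    """SGD epochs over (X, y); per-epoch cost records (and val cost if given).

    Batch order is reshuffled every epoch from a per-epoch derived seed,
    so a fixed ``cfg.seed`` reproduces the run exactly.  Raises
    ``FloatingPointError`` on a non-finite loss.
    """
    opt = Adam(net, lr=cfg.learning_rate)
    n = len(X)
    history: list[dict] = []
    for epoch in range(epochs):
        rng = np.random.default_rng((cfg.seed, epoch))
        order = rng.permutation(n)
        costs, bces, dices = [], [], []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            z = net.forward_logits(X[idx], training=True)
            total, bce, dice, dz = loss_and_grad_from_logits(
                z, y[idx], cfg.bce_weight, cfg.dice_weight, cfg.dice_eps
            )
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch + 1}, batch {start // cfg.batch_size}: "
                    f"bce={bce}, dice={dice}"
                )
            net.backward(dz)
            opt.step()
            costs.append(total)
            bces.append(bce)
            dices.append(dice)
        rec = {
            "epoch": epoch + 1,
            "train_cost": float(np.mean(costs)),
            "train_bce": float(np.mean(bces)),
            "train_dice": float(np.mean(dices)),
        }
        if X_val is not None:
            p = net.predict_proba(X_val, batch_size=cfg.batch_size)
            rec["val_cost"] = bce_dice_loss(
                p, y_val, cfg.bce_weight, cfg.dice_weight, cfg.dice_eps
            )
        history.append(rec)
    return history


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    labels: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[TrainingHistory, int]:
    """k-fold cross-validation over an (already augmented/balanced) set.

    Folds are stratified on the per-slice ascites flag.  Returns the
    history and the selected (1-based) best epoch.
    """
    folds = make_folds(labels, train_config.k_folds, train_config.seed)
    history = TrainingHistory()
    for fold_id in range(train_config.k_folds):
        val = folds == fold_id
        net = build_model(
            ModelConfig(**{**_cfg_dict(model_config), "seed": model_config.seed + fold_id})
        )
        fold_cfg = TrainConfig(**{**asdict(train_config), "seed": train_config.seed + fold_id})
        records = train_loop(
            net,
            X[~val],
            y[~val],
            fold_cfg,
            epochs=train_config.max_epochs,
            X_val=X[val],
            y_val=y[val],
        )
        history.folds.append(records)
    best_epoch = select_best_epoch(history.mean_validation_cost())
    return history, best_epoch


def _cfg_dict(config: ModelConfig) -> dict:
    return asdict(config)


def train_final(
    X: np.ndarray,
    y: np.ndarray,
    model_config: ModelConfig,
    train_config: TrainConfig,
    epochs: int,
) -> ResUNet:
    """Train one model on the full training set for ``epochs`` epochs."""
    if len(X) == 0:
        raise ValueError("cannot train on an empty dataset")
    net = build_model(model_config)
    train_loop(net, X, np.asarray(y, dtype=np.float32), train_config, epochs=epochs)
    return net


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(
    net: ResUNet,
    path: str | Path,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    epochs: int | None = None,
) -> None:
    """Weights + configuration in one .npz; loading round-trips bit-for-bit."""
    meta = {
        "model_config": asdict(model_config),
        "train_config": asdict(train_config) if train_config else None,
        "epochs": epochs,
    }
    np.savez(str(path), __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **net.state_dict())


def load_checkpoint(path: str | Path) -> tuple[ResUNet, dict]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    config = ModelConfig(**meta["model_config"])
    net = build_model(config)
    net.load_state_dict(state)
    return net, meta
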