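"""Training loop: Adam with L2 weight decay, reduce-on-plateau learning
rate, early stopping on the monitored accuracy, best-checkpoint restore.
No data augmentation is applied anywhere in the loop."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attnseg import AttentionSegNet
from .nn import Tensor


class TrainingDivergedError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    lr: float = 0.1               # published default; 1e-2..1e-3 is safer in practice
    batch_size: int = 8
    weight_decay: float = 1e-3
    max_epochs: int = 150
    patience: int = 30            # early-stopping patience, epochs
    monitor: str = "train_acc"    # or "val_acc"
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    min_lr: float = 1e-6
    seed: int = 0

    def validate(self):
        if min(self.lr, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("lr, batch size, epochs and patience must be positive")
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max epochs")
        if self.monitor not in ("train_acc", "val_acc"):
            raise ValueError("monitor must be train_acc or val_acc")


@dataclass
class TrainHistory:
    loss: list = field(default_factory=list)
    train_acc: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    val_acc: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1

    def __len__(self):
        return len(self.loss)

    def to_csv(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["epoch", "loss", "train_acc", "val_loss", "val_acc", "lr"])
            for i in range(len(self.loss)):
                w.writerow([i, self.loss[i], self.train_acc[i],
                            self.val_loss[i], self.val_acc[i], self.lr[i]])


def recalibrate_batchnorm(net, X: np.ndarray, batch_size: int = 8,
                          max_batches: int = 8):
    """Re-estimate batch-norm running statistics with the current weights.

    Short runs leave the exponential running estimates far behind the
    parameters, which wrecks inference-mode predictions; an equal-weight
    pass over a few training batches fixes the mismatch.
    """
    from .nn.layers import BatchNorm2d

    bns = [m for m in net.modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    was_training = net.training
    net.train()
    try:
        with nn.no_grad():
            n_batches = min(max_batches, int(np.ceil(len(X) / batch_size)))
            for i in range(n_batches):
                for bn in bns:
                    bn.momentum = 1.0 / (i + 1)  # equal-weight cumulative mean
                net.forward(Tensor(X[i * batch_size:(i + 1) * batch_size]))
    finally:
        for bn in bns:
            bn.momentum = 0.1
        net.train(was_training)


def evaluate_epoch(net: AttentionSegNet, X: np.ndarray, y: np.ndarray,
                   batch_size: int = 8):
    """Mean per-pixel cross-entropy and pixel accuracy, no parameter updates."""
    if len(X) == 0:
        raise ValueError("empty tile set")
    was_training = net.training
    net.eval()
    total_loss = 0.0
    correct = 0
    n_pix = 0
    try:
        with nn.no_grad():
            for i in range(0, len(X), batch_size):
                xb, yb = X[i:i + batch_size], y[i:i + batch_size]
                logits = net.forward(Tensor(xb))
                loss, probs = nn.softmax_cross_entropy(logits, yb)
                pix = yb.size
                total_loss += float(loss.data) * pix
                correct += int((probs.argmax(axis=1) == yb).sum())
                n_pix += pix
    finally:
        net.train(was_training)
    return total_loss / n_pix, correct / n_pix


def train(net: AttentionSegNet, train_data, val_data, cfg: TrainConfig):
    """Optimize per-pixel cross-entropy; returns (net at best epoch, history).

    `train_data` / `val_data` are (X, y) pairs with X in NCHW float32 and y
    integer class rasters.  Early stopping halts when the monitored accuracy
    has not improved for `cfg.patience` consecutive epochs; the parameters
    from the best epoch are restored before returning.
    """
    cfg.validate()
    Xtr, ytr = train_data
    if len(Xtr) == 0:
        raise ValueError("empty training tile set")
    if ytr.max() >= net.cfg.num_classes:
        raise ValueError("label value outside configured class count")
    Xval, yval = val_data if val_data is not None else (None, None)

    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, factor=cfg.plateau_factor,
                                 patience=cfg.plateau_patience, min_lr=cfg.min_lr)
    history = TrainHistory()
    best_metric = -np.inf
    best_state = None
    epochs_since_best = 0

    for epoch in range(cfg.max_epochs):
        net.train()
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        correct = 0
        n_pix = 0
        for i in range(0, len(order), cfg.batch_size):
            sel = order[i:i + cfg.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            logits = net.forward(Tensor(xb))
            loss, probs = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} (lr={opt.lr}); "
                    "lower the learning rate")
            opt.zero_grad()
            loss.backward()
            opt.step()
            pix = yb.size
            epoch_loss += float(loss.data) * pix
            correct += int((probs.argmax(axis=1) == yb).sum())
            n_pix += pix
        train_loss = epoch_loss / n_pix
        train_acc = correct / n_pix
        if Xval is not None and len(Xval):
            val_loss, val_acc = evaluate_epoch(net, Xval, yval, cfg.batch_size)
        else:
            val_loss, val_acc = np.nan, np.nan

        history.loss.append(train_loss)
        history.train_acc.append(train_acc)
        history.val_loss.append(val_loss)
        history.val_acc.append(val_acc)
        history.lr.append(opt.lr)
        sched.step(train_loss)

        monitored = train_acc if cfg.monitor == "train_acc" else val_acc
        if monitored > best_metric + 1e-12:
            best_metric = monitored
            best_state = net.state_dict()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if epochs_since_best >= cfg.patience:
            break
    history.stopped_epoch = len(history.loss) - 1
    if best_state is not None:
        net.load_state_dict(best_state)
    recalibrate_batchnorm(net, Xtr, cfg.batch_size)
    return net, history
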