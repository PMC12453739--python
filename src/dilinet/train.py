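"""Optimization protocol: splits, BCE loss, SGD with momentum, plateau
learning-rate scheduling, early stopping.

The data are partitioned 90/10 into development and test, and the
development part again 90/10 into training and validation, with round-half-up
sizes (for 1,919 records this gives 1,554/173/192). Optimization is SGD
(lr 0.001, momentum 0.9, weight decay 1e-5) on binary cross-entropy over
shuffled mini-batches of 16, for at most 40 epochs with early stopping
(patience 5) on the validation loss; the learning rate is halved after 3
stagnant validation epochs (floor 1e-6) and the weights of the best
validation epoch are restored at the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np

from .autograd import Tensor
from .model import DiliClassifier, ModelConfig

__all__ = ["TrainConfig", "SplitIndices", "split_dataset", "bce_loss", "train_model", "fit"]

EPS_CLIP = 1e-7


@dataclass
class TrainConfig:
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-5
    batch_size: int = 16
    max_epochs: int = 40
    early_stop_patience: int = 5
    improvement_threshold: float = 1e-4
    scheduler_factor: float = 0.5
    scheduler_patience: int = 3
    min_lr: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.early_stop_patience < 1 or self.scheduler_patience < 1:
            raise ValueError("patience values must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SplitIndices:
    """Disjoint train/validation/test index arrays covering the dataset."""

    train: np.ndarray
    val: np.ndarray
    test: np.ndarray


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(n: int, seed: int) -> SplitIndices:
    """Shuffled 90/10 test split, then 90/10 validation split of the remainder.

    Sizes depend only on ``n`` (round-half-up at each cut); membership is
    shuffled by ``seed``. No stratification.
    """
    n_test = _round_half_up(0.10 * n)
    m = n - n_test
    n_val = _round_half_up(0.10 * m)
    n_train = m - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n={n} too small for non-empty train/val/test splits")
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(train=np.sort(perm[:n_train]),
                        val=np.sort(perm[n_train:n_train + n_val]),
                        test=np.sort(perm[n_train + n_val:]))


def bce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy of probabilities against 0/1 labels.

    Probabilities are clipped to [1e-7, 1 - 1e-7] before the logs.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if probs.shape != labels.shape:
        raise ValueError("probs and labels must have equal length")
    if probs.size == 0:
        raise ValueError("empty batch")
    p = np.clip(probs, EPS_CLIP, 1.0 - EPS_CLIP)
    return float(-np.mean(labels * np.log(p) + (1.0 - labels) * np.log1p(-p)))


def _bce_with_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    # mean(softplus(z) - y*z), the numerically stable logit-space BCE
    y = Tensor(np.asarray(labels, dtype=np.float64))
    return (logits.softplus() - y * logits).mean()


class _SGD:
    """SGD with classical momentum and coupled L2 weight decay."""

    def __init__(self, params: list[Tensor], cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.lr = cfg.lr
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self.velocity):
            grad = p.grad if p.grad is not None else 0.0
            grad = grad + self.cfg.weight_decay * p.data
            v *= self.cfg.momentum
            v += grad
            p.data = p.data - self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _eval_loss(model: DiliClassifier, x: np.ndarray, y: np.ndarray) -> float:
    return bce_loss(model.predict_proba(x), y.astype(float))


def fit(x: np.ndarray, y: np.ndarray, split: SplitIndices,
        mcfg: ModelConfig | None = None, tcfg: TrainConfig | None = None):
    """Train a classifier on pre-featurized inputs.

    Returns ``(model, history)`` where ``history`` is a list of per-epoch
    dicts (epoch, train_loss, val_loss, lr). All randomness — weight
    initialization, batch shuffling, dropout — derives from
    ``tcfg.seed`` through independent child streams.
    """
    mcfg = mcfg or ModelConfig()
    tcfg = tcfg or TrainConfig()
    if len(split.train) == 0 or len(split.val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    init_ss, shuffle_ss, dropout_ss = np.random.SeedSequence(tcfg.seed).spawn(3)
    model = DiliClassifier(mcfg, np.random.default_rng(init_ss))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    opt = _SGD(model.parameters(), tcfg)

    x_train, y_train = x[split.train], y[split.train]
    x_val, y_val = x[split.val], y[split.val]

    history: list[dict] = []
    best_val = np.inf
    best_state = None
    best_epoch = -1
    stall_stop = 0
    stall_sched = 0
    for epoch in range(1, tcfg.max_epochs + 1):
        order = shuffle_rng.permutation(len(x_train))
        total, count = 0.0, 0
        for start in range(0, len(order), tcfg.batch_size):
            idx = order[start:start + tcfg.batch_size]
            opt.zero_grad()
            logits = model._forward_graph(x_train[idx], train=True, rng=dropout_rng)
            loss = _bce_with_logits(logits, y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting (lr={opt.lr})")
            loss.backward()
            opt.step()
            total += float(loss.data) * len(idx)
            count += len(idx)
        train_loss = total / count
        val_loss = _eval_loss(model, x_val, y_val)
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - tcfg.improvement_threshold:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            stall_stop = 0
            stall_sched = 0
        else:
            stall_stop += 1
            stall_sched += 1
            if stall_sched >= tcfg.scheduler_patience:
                opt.lr = max(opt.lr * tcfg.scheduler_factor, tcfg.min_lr)
                stall_sched = 0
            if stall_stop >= tcfg.early_stop_patience:
                break
    if best_state is None:  # no epoch improved on +inf: keep the last state
        best_state = model.state_dict()
        best_epoch = history[-1]["epoch"]
    model.load_state_dict(best_state)
    model.best_epoch = best_epoch
    return model, history


def train_model(compounds, split: SplitIndices, mcfg: ModelConfig | None = None,
                tcfg: TrainConfig | None = None):
    """Featurize a compound list and train (SMILES route)."""
    from .featurize import featurize_compounds

    mcfg = mcfg or ModelConfig()
    mode = "fold" if mcfg.input_mode == "fold" else "raw"
    x, y = featurize_compounds(compounds, mode=mode)
    return fit(x, y, split, mcfg, tcfg)
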