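"""Subject-disjoint cross-validated training.

All segments of a subject live entirely on one side of every train/test
split, so the network is always evaluated on people it has never seen — the
split that matters for physiological reconstruction, where per-subject
morphology is easy to memorize.  Training uses Adam with cosine-annealed
learning rate, early stopping on a subject-disjoint validation slice carved
from the training fold, and a per-segment z-normalization of both the radar
cardiac input and the target ECG (the network predicts normalized
morphology; amplitude calibration is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .model import ModelConfig, RadarEcgNet, mse_loss, rmse_loss
from .synthdata import RadarEcgDataset, SignalSegment

__all__ = ["TrainConfig", "split_subject_kfold", "cosine_lr", "train_fold",
           "znorm", "segment_tensors", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.001
    epochs: int = 300
    batch_size: int = 64
    k_folds: int = 5
    patience: int = 20
    lr_min: float = 1e-6
    val_fraction: float = 0.10    # fraction of training subjects held out
    seed: int = 0
    loss: str = "rmse"

    def validate(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.loss not in ("rmse", "mse"):
            raise ValueError("loss must be 'rmse' or 'mse'")


def split_subject_kfold(subject_ids: list[str], k: int,
                        seed: int) -> list[tuple[list[str], list[str]]]:
    """Shuffled k-fold partition of subjects into (train_ids, test_ids) pairs.

    Every subject appears in exactly one test fold; fold sizes differ by at
    most one subject.  Deterministic under ``seed``.
    """
    subjects = sorted(set(subject_ids))
    if len(subjects) < k:
        raise ValueError(f"{len(subjects)} subjects cannot form {k} folds")
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    folds = [list(f) for f in np.array_split(order, k)]
    out = []
    for i in range(k):
        test = sorted(folds[i])
        train = sorted(s for j, f in enumerate(folds) if j != i for s in f)
        out.append((train, test))
    return out


def cosine_lr(epoch: int, total_epochs: int, lr0: float, lr_min: float) -> float:
    """Cosine annealing: lr0 at epoch 0, lr_min at the final epoch."""
    if total_epochs <= 1:
        return lr0
    frac = epoch / (total_epochs - 1)
    return lr_min + (lr0 - lr_min) * (1.0 + math.cos(math.pi * frac)) / 2.0


def znorm(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _segment_input(seg: SignalSegment) -> np.ndarray:
    x = seg.x_card if seg.x_card is not None else seg.displacement
    return znorm(np.asarray(x, dtype=float))


def _segment_target(seg: SignalSegment) -> np.ndarray:
    y = seg.ecg_clean if seg.ecg_clean is not None else seg.ecg
    return znorm(np.asarray(y, dtype=float))


def segment_tensors(segments: list[SignalSegment]) -> tuple[np.ndarray, np.ndarray]:
    """Stacked (inputs, targets), z-normalized per segment.

    Inputs prefer the preprocessed cardiac trace (``x_card``) and fall back to
    the true displacement; targets prefer ``ecg_clean`` over the raw ECG.
    """
    X = np.stack([_segment_input(s) for s in segments])
    Y = np.stack([_segment_target(s) for s in segments])
    return X, Y


def predict(model: RadarEcgNet, segments: list[SignalSegment],
            batch_size: int = 32) -> np.ndarray:
    """Reconstructed ECG for each segment (model in eval mode)."""
    model.eval()
    X, _ = segment_tensors(segments)
    outs = []
    for i in range(0, len(X), batch_size):
        outs.append(model(Tensor(X[i:i + batch_size])).data)
    return np.concatenate(outs, axis=0)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int | None = None
    best_epoch: int = 0


def _eval_loss(model: RadarEcgNet, X: np.ndarray, Y: np.ndarray,
               loss_name: str, batch_size: int) -> float:
    model.eval()
    fn = rmse_loss if loss_name == "rmse" else mse_loss
    tot, n = 0.0, 0
    for i in range(0, len(X), batch_size):
        xb, yb = X[i:i + batch_size], Y[i:i + batch_size]
        tot += float(fn(model(Tensor(xb)), Tensor(yb)).data) * len(xb)
        n += len(xb)
    model.train()
    return tot / n


def train_fold(dataset: RadarEcgDataset, fold: tuple[list[str], list[str]],
               cfg: TrainConfig, mcfg: ModelConfig,
               model: RadarEcgNet | None = None,
               ) -> tuple[RadarEcgNet, TrainHistory]:
    """Train one cross-validation fold; returns the best-validation model.

    A subject-disjoint validation slice (``val_fraction`` of the training
    subjects, at least one) is held out of the parameter updates for early
    stopping; test subjects never touch training in any way (asserted).
    """
    cfg.validate()
    mcfg.validate()
    train_ids, test_ids = fold
    if not train_ids:
        raise ValueError("empty training fold")
    if set(train_ids) & set(test_ids):
        raise ValueError("train/test subject sets intersect")
    missing = set(train_ids) - set(dataset.subject_ids)
    if missing:
        raise ValueError(f"fold subjects not in dataset: {sorted(missing)}")

    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(train_ids))))
    if n_val >= len(train_ids):
        raise ValueError("not enough training subjects for a validation slice")
    perm = rng.permutation(len(train_ids))
    val_ids = sorted(train_ids[i] for i in perm[:n_val])
    fit_ids = sorted(train_ids[i] for i in perm[n_val:])
    assert not (set(fit_ids) | set(val_ids)) & set(test_ids)

    fit_segs = dataset.subset(fit_ids).segments
    val_segs = dataset.subset(val_ids).segments
    Xf, Yf = segment_tensors(fit_segs)
    Xv, Yv = segment_tensors(val_segs)

    if model is None:
        model = RadarEcgNet(mcfg, seed=int(rng.integers(2 ** 31)))
    model.train()
    opt = ad.Adam(model.parameters(), lr=cfg.lr)
    loss_fn = rmse_loss if cfg.loss == "rmse" else mse_loss

    hist = TrainHistory()
    best_val = math.inf
    best_state = [a.copy() for a in model.state_arrays()]
    since_best = 0
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr, cfg.lr_min)
        order = rng.permutation(len(Xf))
        tot, nseen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            loss = loss_fn(model(Tensor(Xf[idx])), Tensor(Yf[idx]))
            lval = float(loss.data)
            if not math.isfinite(lval):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step(lr=lr)
            tot += lval * len(idx)
            nseen += len(idx)
        vloss = _eval_loss(model, Xv, Yv, cfg.loss, cfg.batch_size)
        hist.train_loss.append(tot / nseen)
        hist.val_loss.append(vloss)
        hist.lr.append(lr)
        if vloss < best_val - 1e-7:
            best_val = vloss
            best_state = [a.copy() for a in model.state_arrays()]
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                hist.stopped_epoch = epoch
                break
    model.load_state_arrays(best_state)
    model.eval()
    return model, hist
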