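"""Training loop: rebalanced epochs, augmentation, Adam, early stopping.

Each training epoch draws a fresh rebalanced index multiset, iterates it in
shuffled minibatches, augments every window with fresh random draws, and
updates the weights by Adam with global-norm gradient clipping and the
warm-up/cool-down learning-rate protocol.  After every epoch the macro F1
on the (never rebalanced, never augmented) validation set is computed;
training stops when it has not strictly improved for ``patience``
consecutive epochs (but never before ``min_epochs``), and the weights from
the best-scoring epoch are returned.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .augment import AugmentationParams, augment
from .errors import ConfigError, DataError
from .evaluation import confusion
from .nn.layers import DTYPE
from .nn.network import SleepNet
from .nn.optim import (
    OptimizerState,
    TrainConfig,
    adam_update,
    clip_gradients,
    learning_rate,
    nll_l2_loss,
)
from .preprocess import ContextWindow
from .rebalance import RebalanceSpec, make_training_view
from .stages import Stage

__all__ = ["EarlyStopper", "train"]


class EarlyStopper:
    """Strict-improvement early stopping with a minimum-epoch floor.

    ``update(epoch, score)`` records the running best (strict increase) and
    returns True when training should stop: either ``patience`` consecutive
    epochs without improvement have passed (and ``epoch >= min_epochs``), or
    ``epoch >= max_epochs``.
    """

    def __init__(self, min_epochs: int, max_epochs: int, patience: int):
        if min_epochs > max_epochs or patience < 1:
            raise ConfigError("need min_epochs <= max_epochs and patience >= 1")
        self.min_epochs = min_epochs
        self.max_epochs = max_epochs
        self.patience = patience
        self.best_score = -np.inf
        self.best_epoch = 0
        self._since_best = 0

    def update(self, epoch: int, score: float) -> bool:
        if score > self.best_score:
            self.best_score = score
            self.best_epoch = epoch
            self._since_best = 0
        else:
            self._since_best += 1
        if epoch >= self.max_epochs:
            return True
        return epoch >= self.min_epochs and self._since_best >= self.patience


def _batch_signals(windows: list[ContextWindow], idx: np.ndarray,
                   params: AugmentationParams | None,
                   rng: np.random.Generator) -> np.ndarray:
    rows = []
    for i in idx:
        w = windows[i]
        if params is not None and params.any_active:
            rows.append(augment(w, params, rng))
        else:
            rows.append(w.signal)
    return np.stack(rows).astype(DTYPE)


def _validation_macro_f1(model: SleepNet, X_val: np.ndarray,
                         y_val: np.ndarray) -> tuple[float, dict[int, float]]:
    _, pred = model.predict(X_val)
    report = confusion(y_val, pred, classes=model.classes_)
    per_class = {
        int(c): float(f) for c, f in zip(report.classes, report.f1)
    }
    return report.f1_mean, per_class


def train(model: SleepNet, train_windows: list[ContextWindow],
          X_val: np.ndarray, y_val: np.ndarray, cfg: TrainConfig,
          rebalance_spec: RebalanceSpec | None = None,
          augment_params: AugmentationParams | None = None,
          log=None) -> tuple[SleepNet, pd.DataFrame]:
    """Train ``model`` in place; returns it with best-epoch weights restored
    plus a per-epoch history table (lr, train loss, per-class and macro
    validation F1).

    All randomness (rebalancing, shuffling, augmentation draws, dropout)
    derives from ``cfg.seed``.
    """
    if not train_windows:
        raise DataError("empty training set")
    if len(X_val) == 0:
        raise DataError("empty validation set")

    ss = np.random.SeedSequence(cfg.seed)
    rng_view, rng_aug, rng_drop = (np.random.default_rng(c) for c in ss.spawn(3))

    labels = np.array([w.label for w in train_windows])
    class_to_neuron = {int(c): j for j, c in enumerate(model.classes_)}
    unknown = set(np.unique(labels)) - set(class_to_neuron)
    if unknown:
        raise ConfigError(f"training labels {unknown} missing from model classes")

    view = make_training_view(labels, rebalance_spec, rng_view)
    params = model.params()
    decayed = [p for p in params if p.decay]
    states = [OptimizerState.zeros_like(p.value) for p in params]
    stopper = EarlyStopper(cfg.min_epochs, cfg.max_epochs, cfg.patience)
    best_weights = model.get_weights()
    history = []

    for epoch in range(1, cfg.max_epochs + 1):
        eta = learning_rate(epoch, cfg)
        idx = next(view)
        losses = []
        for b in range(0, len(idx), cfg.batch_size):
            batch = idx[b : b + cfg.batch_size]
            if len(batch) == 0:
                continue
            X = _batch_signals(train_windows, batch, augment_params, rng_aug)
            y = np.array([class_to_neuron[int(labels[i])] for i in batch])
            n_b = len(batch)

            logits = model.forward(X, train=True, rng=rng_drop)
            z = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(z)
            probs = e / e.sum(axis=1, keepdims=True)
            losses.append(
                nll_l2_loss(probs, y, [p.value for p in decayed], cfg.l2_lambda)
            )
            dlogits = probs.copy()
            dlogits[np.arange(n_b), y] -= 1.0
            model.backward(dlogits / n_b)
            for p in decayed:  # d/dw of lambda/(2 N_b) * w^2
                p.grad += (cfg.l2_lambda / n_b) * p.value

            grads = clip_gradients([p.grad for p in params], cfg.clip_norm)
            for p, g, k in zip(params, grads, range(len(params))):
                p.value[...], states[k] = adam_update(
                    p.value, g, states[k], eta, cfg.beta1, cfg.beta2, cfg.epsilon
                )

        val_f1, per_class = _validation_macro_f1(model, X_val, y_val)
        row = {
            "epoch": epoch,
            "lr": eta,
            "train_loss": float(np.mean(losses)),
            "val_macro_f1": val_f1,
        }
        row.update({f"val_f1_{Stage(c).name}": v for c, v in per_class.items()})
        history.append(row)
        if log is not None:
            log(row)

        improved = val_f1 > stopper.best_score
        stop = stopper.update(epoch, val_f1)
        if improved:
            best_weights = model.get_weights()
        if stop:
            break

    model.set_weights(best_weights)
    return model, pd.DataFrame(history)
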