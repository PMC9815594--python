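"""Training loop: summed-squared-error loss, plateau LR decay, early stop.

The loss is the sum over the batch and over pixels of the squared
difference between the network output and the motion-free reference — a sum,
not a mean, so its magnitude grows with batch size and image area.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError, TrainingDivergedError


def sse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Summed squared error over batch and pixels; zero iff identical."""
    d = pred - target
    return float(np.sum(d * d))


class PlateauScheduler:
    """Halve-on-plateau learning-rate schedule plus early-stopping counter.

    ``on_epoch(val_loss)`` returns the learning rate to use next and whether
    training should stop.  The LR is multiplied by ``factor`` whenever the
    validation loss has not improved for ``patience`` consecutive epochs;
    training stops after ``stop_patience`` consecutive non-improving epochs.
    """

    def __init__(self, initial_lr: float, factor: float = 0.5, patience: int = 10,
                 stop_patience: int = 50):
        if not 0.0 < factor < 1.0:
            raise ConfigurationError(f"lr factor must be in (0, 1), got {factor}")
        self.lr = initial_lr
        self.factor = factor
        self.patience = patience
        self.stop_patience = stop_patience
        self.best = np.inf
        self._stall = 0
        self._stop_stall = 0

    def on_epoch(self, val_loss: float) -> tuple[float, bool]:
        if val_loss < self.best:
            self.best = val_loss
            self._stall = 0
            self._stop_stall = 0
        else:
            self._stall += 1
            self._stop_stall += 1
            if self._stall >= self.patience:
                self.lr *= self.factor
                self._stall = 0
        return self.lr, self._stop_stall >= self.stop_patience


def _batched_loss(net, pairs, batch_size: int) -> float:
    total = 0.0
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i : i + batch_size]
        x = np.stack([p[0] for p in chunk])[:, None]
        y = np.stack([p[1] for p in chunk])[:, None]
        total += sse_loss(net.forward(x, train=False), y)
    return total


def train(net, pairs, cfg, val_pairs=None, optimizer_cls=None):
    """Fit ``net`` to (corrupted, reference) pairs with Adam.

    Returns ``(best_state, history)`` where ``history`` is a list of dicts
    with epoch, train loss, validation loss and learning rate.  The state at
    the best validation loss is returned (and left loaded in ``net``).
    """
    from .optim import Adam

    if len(pairs) == 0:
        raise ConfigurationError("training requires at least one image pair")
    if val_pairs is None:
        val_pairs = pairs
    rng = np.random.default_rng(cfg.seed)
    opt = (optimizer_cls or Adam)(net, lr=cfg.initial_lr)
    sched = PlateauScheduler(cfg.initial_lr, cfg.lr_factor, cfg.lr_patience,
                             cfg.early_stop_patience)
    best_val = _batched_loss(net, val_pairs, cfg.batch_size)
    best_state = net.state_dict()
    history = []
    cursor, perm = 0, rng.permutation(len(pairs))
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(pairs))  # reshuffle each epoch
        cursor = 0
        train_loss = 0.0
        for _ in range(cfg.steps_per_epoch):
            take = []
            while len(take) < cfg.batch_size:
                if cursor == len(perm):
                    perm = rng.permutation(len(pairs))
                    cursor = 0
                take.append(perm[cursor])
                cursor += 1
            x = np.stack([pairs[i][0] for i in take])[:, None]
            y = np.stack([pairs[i][1] for i in take])[:, None]
            pred = net.forward(x, train=True)
            y = y.astype(pred.dtype)
            loss = sse_loss(pred, y)
            if not np.isfinite(loss):
                raise TrainingDivergedError(f"non-finite loss at epoch {epoch}")
            train_loss += loss
            net.backward(2.0 * (pred - y))
            opt.step()
        val_loss = _batched_loss(net, val_pairs, cfg.batch_size)
        if val_loss < best_val:
            best_val = val_loss
            best_state = net.state_dict()
        lr, stop = sched.on_epoch(val_loss)
        history.append({
            "epoch": epoch,
            "train_loss": train_loss / cfg.steps_per_epoch,
            "val_loss": val_loss,
            "lr": opt.lr,
        })
        opt.lr = lr
        if stop:
            break
    net.load_state_dict(best_state)
    return best_state, history
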