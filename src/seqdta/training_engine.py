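"""Training: loss, AdamW with decoupled weight decay, early stopping,
k-fold cross-validation and ensemble prediction.

The AdamW step follows the decoupled form

    g_t   = grad + w * x_{t-1}                (w = 0 by default: decay is
    v_t   = b1 v_{t-1} + (1-b1) g_t            handled by the lambda term,
    s_t   = b2 s_{t-1} + (1-b2) g_t^2          not folded into the gradient)
    vhat  = v_t / (1 - b1^t)
    shat  = s_t / (1 - b2^t)
    x_t   = x_{t-1} - eta_t * (alpha * vhat / (sqrt(shat) + eps)
                               + lambda * x_{t-1})

Early stopping fires when the training loss has not decreased for three
consecutive epochs while sitting below the validation loss, or at the
epoch cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .model import AffinityModel


# ---------------------------------------------------------------------------
# AdamW
# ---------------------------------------------------------------------------

@dataclass
class OptimizerState:
    """Per-parameter AdamW accumulators and hyperparameters."""

    beta1: float = 0.9
    beta2: float = 0.999
    alpha: float = 1e-4          # base learning rate
    eta: float = 1.0             # schedule multiplier (constant schedule)
    weight_decay: float = 0.0    # lambda in the decoupled decay term
    coupled_decay: float = 0.0   # w: L2 folded into the gradient (off)
    eps: float = 1e-8
    t: int = 0
    v: np.ndarray | float = 0.0
    s: np.ndarray | float = 0.0


def adamw_step(param: np.ndarray | float, gradient: np.ndarray | float,
               state: OptimizerState):
    """One AdamW update; returns (new_param, state) with state advanced."""
    param = np.asarray(param, dtype=np.float64)
    gradient = np.asarray(gradient, dtype=np.float64)
    state.t += 1
    g = gradient + state.coupled_decay * param
    state.v = state.beta1 * state.v + (1.0 - state.beta1) * g
    state.s = state.beta2 * state.s + (1.0 - state.beta2) * g**2
    v_hat = state.v / (1.0 - state.beta1**state.t)
    s_hat = state.s / (1.0 - state.beta2**state.t)
    step = state.eta * (state.alpha * v_hat / (np.sqrt(s_hat) + state.eps)
                        + state.weight_decay * param)
    return param - step, state


class AdamW:
    """AdamW over a list of Parameters, built on :func:`adamw_step`."""

    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, weight_decay: float = 0.0,
                 eta: float = 1.0, eps: float = 1e-8):
        self.params = list(params)
        self.states = [OptimizerState(beta1=beta1, beta2=beta2, alpha=lr,
                                      eta=eta, weight_decay=weight_decay,
                                      eps=eps)
                       for _ in self.params]

    def step(self) -> None:
        for p, st in zip(self.params, self.states):
            if p.grad is None:
                continue
            p.data, _ = adamw_step(p.data, p.grad, st)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


# ---------------------------------------------------------------------------
# Loss and early stopping
# ---------------------------------------------------------------------------

def training_loss(predictions: Tensor, targets: np.ndarray) -> Tensor:
    """Mean squared error over the batch (differentiable)."""
    diff = predictions - Tensor(np.asarray(targets, dtype=np.float64))
    return (diff * diff).mean()


@dataclass
class EarlyStopConfig:
    max_epochs: int = 50
    patience: int = 3

    def __post_init__(self):
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def should_stop(train_losses, val_losses, config: EarlyStopConfig) -> bool:
    """True once the epoch cap is reached, or once the last ``patience``
    epoch-over-epoch training-loss changes are all >= 0 while the current
    training loss sits below the current validation loss."""
    n = len(train_losses)
    if n >= config.max_epochs:
        return True
    if n < config.patience + 1 or not len(val_losses):
        return False
    recent = np.diff(np.asarray(train_losses[-(config.patience + 1):]))
    plateaued = bool(np.all(recent >= 0))
    return plateaued and train_losses[-1] < val_losses[-1]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    k: int
    folds: list = field(default_factory=list)
    seed: int = 0

    def validation_indices(self, fold: int) -> np.ndarray:
        return np.asarray(self.folds[fold])

    def training_indices(self, fold: int) -> np.ndarray:
        return np.concatenate([self.folds[j] for j in range(self.k) if j != fold])


def make_folds(n: int, k: int, seed: int) -> FoldPlan:
    """Seeded shuffle then round-robin assignment into k balanced folds."""
    if not 1 <= k <= n:
        raise ValueError("need 1 <= k <= n")
    order = np.random.default_rng(seed).permutation(n)
    folds = [order[j::k].tolist() for j in range(k)]
    return FoldPlan(k=k, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# Trainer
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    train_losses: list
    val_losses: list
    epochs_run: int
    stopped_early: bool


class Trainer:
    """Mini-batch trainer for :class:`AffinityModel`.

    Targets are standardized to zero mean / unit variance on the training
    set (the scale is stored in the model and undone by ``predict``), so
    the randomly initialized head starts near the data rather than a
    fixed offset away from it.
    """

    def __init__(self, lr: float = 1e-4, weight_decay: float = 0.0,
                 batch_size: int = 32, seed: int = 0,
                 early_stop: EarlyStopConfig | None = None,
                 standardize_targets: bool = True):
        self.lr = lr
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.seed = seed
        self.early_stop = early_stop or EarlyStopConfig()
        self.standardize_targets = standardize_targets

    def fit(self, model: AffinityModel, batch: dict,
            val_batch: dict | None = None, log=None) -> TrainResult:
        """Train ``model`` on arrays ``batch`` with keys ``protein``,
        ``ligand``, ``affinity`` and optionally ``pocket``."""
        rng = np.random.default_rng(self.seed)
        y = np.asarray(batch["affinity"], dtype=np.float64)
        if self.standardize_targets:
            model.target_mean = float(y.mean())
            model.target_std = float(y.std()) or 1.0
        y_std = (y - model.target_mean) / model.target_std
        n = len(y)
        opt = AdamW(model.parameters(), lr=self.lr,
                    weight_decay=self.weight_decay)
        train_losses: list[float] = []
        val_losses: list[float] = []
        stopped = False
        epoch = 0
        while True:
            epoch += 1
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                pred = model.forward(
                    batch["protein"][idx], batch["ligand"][idx],
                    batch.get("pocket")[idx] if batch.get("pocket") is not None else None,
                    train=True, rng=rng)
                loss = training_loss(pred, y_std[idx])
                model.zero_grad()
                loss.backward()
                model.freeze_padding()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            train_losses.append(epoch_loss / n)
            if val_batch is not None:
                vp = model.predict(val_batch["protein"], val_batch["ligand"],
                                   val_batch.get("pocket"))
                vres = (vp - np.asarray(val_batch["affinity"])) / model.target_std
                val_losses.append(float(np.mean(vres**2)))
            if log is not None:
                log({"epoch": epoch, "train_loss": train_losses[-1],
                     "val_loss": val_losses[-1] if val_losses else None})
            if should_stop(train_losses, val_losses, self.early_stop):
                stopped = epoch < self.early_stop.max_epochs
                break
        return TrainResult(train_losses, val_losses, epoch, stopped)


def ensemble_predict(models, protein_idx, ligand_idx, pocket_idx=None) -> np.ndarray:
    """Arithmetic mean of the member models' predictions."""
    models = list(models)
    if not models:
        raise ValueError("ensemble requires at least one model")
    preds = [m.predict(protein_idx, ligand_idx, pocket_idx) for m in models]
    return np.mean(preds, axis=0)
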