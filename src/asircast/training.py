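"""Model fitting and regression metrics.

Training minimizes MSE over all group outputs jointly with Adam, cosine
learning-rate annealing, global-norm gradient clipping and early stopping
on a time-ordered validation tail; the best-validation parameters are
restored before returning.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .features import WindowedDataset
from .network import DualPathwayModel, Hyperparameters, ensemble_predict

__all__ = [
    "TrainingConfig",
    "MetricsReport",
    "Adam",
    "cosine_lr",
    "train_model",
    "TrainedModel",
    "train_ensemble",
    "evaluate",
    "run_ablation",
    "ABLATION_VARIANTS",
]


@dataclass
class TrainingConfig:
    max_epochs: int = 500
    batch_size: int = 16
    early_stop_patience: int = 20
    gradient_clip_norm: float = 1.0
    seed: int = 0
    validation_years: int = 4  # last N target years of the training partition
    lr_floor_fraction: float = 0.01  # cosine anneal terminus: lr / 100

    def __post_init__(self):
        if self.early_stop_patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.validation_years < 1:
            raise ValueError("validation tail must cover at least one target year")


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params: list, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            m_hat = self.m[i] / (1 - self.b1 ** self.t)
            v_hat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(epoch: int, max_epochs: int, lr0: float, floor_fraction: float = 0.01) -> float:
    """Cosine annealing from lr0 down to lr0*floor_fraction over max_epochs."""
    lr_min = lr0 * floor_fraction
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * epoch / max_epochs))


def clip_gradients(params: list, max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the post-clip global norm.
    """
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
        return max_norm
    return norm


@dataclass
class TrainedModel:
    model: DualPathwayModel
    history: list  # per-epoch dicts: epoch, train_loss, val_loss, lr, grad_norm
    best_epoch: int
    best_val_loss: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def _mse_loss(model: DualPathwayModel, X: np.ndarray, y: np.ndarray,
              training: bool, rng=None) -> Tensor:
    pred = model.forward(X, training=training, rng=rng)
    err = pred - Tensor(y)
    return (err ** 2).mean()


def train_model(train: WindowedDataset, hp: Hyperparameters, cfg: TrainingConfig,
                model: DualPathwayModel | None = None) -> TrainedModel:
    """Fit one ensemble member on a windowed training set.

    The validation slice is the last ``cfg.validation_years`` distinct target
    years of ``train`` (a time-ordered tail, so no future sample influences
    fitting).  Deterministic for a fixed seed.
    """
    if train.n_samples == 0:
        raise ValueError("empty training set")
    years = np.unique(train.target_years)
    if len(years) <= cfg.validation_years:
        raise ValueError("training set too short to carve out the validation tail")
    val_cut = years[-cfg.validation_years]
    val_mask = train.target_years >= val_cut
    fit, val = train.subset(~val_mask), train.subset(val_mask)

    if model is None:
        model = DualPathwayModel(n_features=train.inputs.shape[2],
                                 n_groups=train.targets.shape[1],
                                 window=train.window, hp=hp, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    params = model.parameters()
    opt = Adam(params, lr=hp.learning_rate)

    best_state = model.state_arrays()
    best_val = math.inf
    best_epoch = -1
    epochs_since_improve = 0
    history = []
    n = fit.n_samples
    for epoch in range(cfg.max_epochs):
        opt.lr = cosine_lr(epoch, cfg.max_epochs, hp.learning_rate, cfg.lr_floor_fraction)
        order = rng.permutation(n)
        epoch_loss = 0.0
        max_norm_seen = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            opt.zero_grad()
            loss = _mse_loss(model, fit.inputs[idx], fit.targets[idx], training=True, rng=rng)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; aborting")
            loss.backward()
            norm = clip_gradients(params, cfg.gradient_clip_norm)
            max_norm_seen = max(max_norm_seen, norm)
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n
        val_loss = float(_mse_loss(model, val.inputs, val.targets, training=False).data)
        history.append({"epoch": epoch, "train_loss": epoch_loss, "val_loss": val_loss,
                        "lr": opt.lr, "grad_norm": max_norm_seen})
        if val_loss < best_val:
            best_val = val_loss
            best_epoch = epoch
            best_state = model.state_arrays()
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve > cfg.early_stop_patience:
                break
    model.load_state_arrays(best_state)
    return TrainedModel(model=model, history=history, best_epoch=best_epoch,
                        best_val_loss=best_val)


def train_ensemble(train: WindowedDataset, hp: Hyperparameters, cfg: TrainingConfig) -> list:
    """Train ``hp.ensemble_size`` members from perturbed seeds (base_seed + m)."""
    members = []
    for m in range(hp.ensemble_size):
        member_cfg = TrainingConfig(**{**cfg.__dict__, "seed": cfg.seed + m})
        members.append(train_model(train, hp, member_cfg))
    return members


# -- metrics ---------------------------------------------------------------


@dataclass
class MetricsReport:
    mae: float
    mse: float
    rmse: float
    mape: float  # fraction: 0.15 means 15%
    r2: float
    n: int
    mape_excluded: int = 0  # elements with y_true == 0, excluded from MAPE
    per_group: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"mae": self.mae, "mse": self.mse, "rmse": self.rmse,
                "mape": self.mape, "r2": self.r2, "n": self.n,
                "mape_excluded": self.mape_excluded}


def evaluate(y_true: np.ndarray, y_pred: np.ndarray,
             group_keys: list | None = None) -> MetricsReport:
    """Pooled MAE / MSE / RMSE / MAPE / R^2 over all samples and groups.

    MAPE is a fraction; elements with a zero true value are excluded from it
    with a warning and counted in ``mape_excluded``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch: {y_true.shape} vs {y_pred.shape}")
    err = y_true - y_pred
    mae = float(np.abs(err).mean())
    mse = float((err ** 2).mean())
    rmse = math.sqrt(mse)
    nonzero = y_true != 0
    excluded = int((~nonzero).sum())
    if excluded:
        warnings.warn(f"MAPE undefined for {excluded} zero-valued element(s); excluded",
                      RuntimeWarning, stacklevel=2)
    mape = float(np.abs(err[nonzero] / y_true[nonzero]).mean()) if nonzero.any() else math.nan
    ss_tot = float(((y_true - y_true.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y_true is constant")
    r2 = 1.0 - float((err ** 2).sum()) / ss_tot
    per_group = {}
    if group_keys is not None and y_true.ndim == 2:
        for gi, key in enumerate(group_keys):
            ge = err[:, gi]
            gt = y_true[:, gi]
            g_nz = gt != 0
            per_group[key] = {
                "mae": float(np.abs(ge).mean()),
                "rmse": float(np.sqrt((ge ** 2).mean())),
                "mape": float(np.abs(ge[g_nz] / gt[g_nz]).mean()) if g_nz.any() else math.nan,
            }
    return MetricsReport(mae=mae, mse=mse, rmse=rmse, mape=mape, r2=r2,
                         n=int(y_true.size), mape_excluded=excluded, per_group=per_group)


# -- ablation table --------------------------------------------------------

# name -> (bidirectional, use_attention, run_pso)
ABLATION_VARIANTS = {
    "LSTM": (False, False, False),
    "BiLSTM": (True, False, False),
    "BiLSTM-Attention": (True, True, False),
    "PSO-BiLSTM": (True, False, True),
    "PSO-BiLSTM-Attention": (True, True, True),
}


def run_ablation(train: WindowedDataset, test: WindowedDataset, hp: Hyperparameters,
                 cfg: TrainingConfig, variants: list | None = None,
                 swarm_config=None, search_space=None,
                 invert=None) -> dict:
    """Train each named configuration on the same split and evaluate on test.

    ``invert`` optionally maps standardized (B, G) arrays back to the rate
    scale before metric computation.  PSO variants run a swarm search first
    when ``swarm_config`` is provided, else fall back to the supplied ``hp``.
    """
    from .pso import optimize_hyperparameters  # local import: avoid cycle

    variants = list(variants or ABLATION_VARIANTS)
    results = {}
    for name in variants:
        if name not in ABLATION_VARIANTS:
            raise ValueError(f"unknown ablation variant {name!r}")
        bidir, attn, pso_on = ABLATION_VARIANTS[name]
        var_hp = Hyperparameters(**{**hp.__dict__, "bidirectional": bidir,
                                    "use_attention": attn})
        if pso_on and swarm_config is not None:
            var_hp, _ = optimize_hyperparameters(train, var_hp, cfg, swarm_config,
                                                 space=search_space)
        members = train_ensemble(train, var_hp, cfg)
        pred = ensemble_predict([t.model for t in members], test.inputs)
        y_true, y_pred = test.targets, pred
        if invert is not None:
            y_true, y_pred = invert(y_true), invert(y_pred)
        results[name] = evaluate(y_true, y_pred, group_keys=test.group_keys)
    return results
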