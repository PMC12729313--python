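"""Dual-pathway forecasting network.

Deep path: per-timestep input projection (affine + batch norm + ReLU) ->
stacked BiLSTM -> multi-scale multi-head attention over lag windows ->
shared ReLU layer -> one affine head per sex-age group.  Linear path: the
time-averaged input through a single projection.  The two are fused by a
learnable convex weight alpha (sigmoid-parameterized), and an ensemble of
independently initialized members is averaged for the final prediction.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, concat, relu, sigmoid, tanh

__all__ = [
    "Hyperparameters",
    "DualPathwayModel",
    "input_projection",
    "lstm_cell_step",
    "bilstm_forward",
    "attention_head",
    "multi_scale_attention",
    "group_heads",
    "residual_fusion",
    "ensemble_predict",
    "scale_mask",
]


@dataclass
class Hyperparameters:
    """Architecture and optimizer knobs; defaults follow the tuned optimum."""

    d_h: int = 64
    n_lstm_layers: int = 2
    dropout: float = 0.15
    learning_rate: float = 0.002
    heads_per_scale: int = 4
    d_a: int | None = None  # attention projection width; defaults to d_h
    d_shared: int | None = None  # shared output layer width; defaults to d_h
    scales: tuple = ((1, 3), (3, 6), (6, 10))
    ensemble_size: int = 3
    bidirectional: bool = True
    use_attention: bool = True
    batchnorm: bool = True

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.d_h < 1 or self.n_lstm_layers < 1 or self.heads_per_scale < 1:
            raise ValueError("d_h, n_lstm_layers and heads_per_scale must be >= 1")
        if self.d_a is None:
            self.d_a = self.d_h
        if self.d_shared is None:
            self.d_shared = self.d_h

    def validate_scales(self, window: int) -> None:
        for lo, hi in self.scales:
            if not (1 <= lo <= hi <= window):
                raise ValueError(f"scale ({lo},{hi}) outside window [1,{window}]")


def scale_mask(window: int, lo: int, hi: int) -> np.ndarray:
    """Boolean mask over window steps whose lag-from-present is in [lo, hi].

    Step index i (0 = oldest) has lag window - i, so lag 1 is the most
    recent year.  Boundary lags shared by adjacent scales appear in both.
    """
    lags = window - np.arange(window)
    return (lags >= lo) & (lags <= hi)


# -- functional building blocks -------------------------------------------


def input_projection(X: Tensor, W: Tensor, b: Tensor, bn: "BatchNorm | None" = None,
                     training: bool = False) -> Tensor:
    """ReLU(X W + b) per timestep, with optional batch norm before the ReLU."""
    X = ad.as_tensor(X)
    if X.shape[-1] != W.shape[0]:
        raise ValueError(f"feature width {X.shape[-1]} does not match W ({W.shape[0]})")
    H = X @ W + b
    if bn is not None:
        B, T, d = H.shape
        H = bn(H.reshape(B * T, d), training=training).reshape(B, T, d)
    return relu(H)


def lstm_cell_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor, w: dict):
    """One LSTM step: forget/input/output gates and cell update.

    Weights act on the concatenation [h_{t-1}, x_t]; each W_* has shape
    (d_h + d_in, d_h).
    """
    z = concat([h_prev, x_t], axis=1)
    f_t = sigmoid(z @ w["W_f"] + w["b_f"])
    i_t = sigmoid(z @ w["W_i"] + w["b_i"])
    c_tilde = tanh(z @ w["W_C"] + w["b_C"])
    c_t = f_t * c_prev + i_t * c_tilde
    o_t = sigmoid(z @ w["W_o"] + w["b_o"])
    h_t = o_t * tanh(c_t)
    return h_t, c_t


def _lstm_direction(H: Tensor, w: dict, d_h: int, reverse: bool) -> list:
    B, T, _ = H.shape
    h = Tensor(np.zeros((B, d_h)))
    c = Tensor(np.zeros((B, d_h)))
    order = range(T - 1, -1, -1) if reverse else range(T)
    outputs: list = [None] * T
    for t in order:
        h, c = lstm_cell_step(H[:, t, :], h, c, w)
        outputs[t] = h
    return outputs


def _dropout(H: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(H.shape) >= p) / (1.0 - p)
    return H * Tensor(mask)


def bilstm_forward(H: Tensor, layers: list, d_h: int, dropout: float = 0.0,
                   training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
    """Stacked (bi)directional LSTM; returns (B, T, 2*d_h) (or (B, T, d_h)).

    Each layer runs a chronological pass and, if bidirectional, a reversed
    pass whose states are concatenated per step.  Inter-layer dropout is
    applied only in training mode.
    """
    B, T, _ = H.shape
    out = H
    for li, layer in enumerate(layers):
        fwd = _lstm_direction(out, layer["forward"], d_h, reverse=False)
        if "backward" in layer:
            bwd = _lstm_direction(out, layer["backward"], d_h, reverse=True)
            steps = [concat([fwd[t], bwd[t]], axis=1) for t in range(T)]
        else:
            steps = fwd
        width = steps[0].shape[1]
        out = concat([s.reshape(B, 1, width) for s in steps], axis=1)
        if training and dropout > 0.0 and li < len(layers) - 1:
            if rng is None:
                raise ValueError("training-mode dropout requires an rng")
            out = _dropout(out, dropout, rng)
    return out


def attention_head(Hseq: Tensor, W_a: Tensor, b_a: Tensor, v_a: Tensor,
                   d_k: float, mask: np.ndarray) -> Tensor:
    """Additive-scored softmax attention over the unmasked steps.

    Scores s_t = tanh(W_a h_t + b_a); logits s_t . v_a / sqrt(d_k); weights
    softmax over unmasked steps (masked steps get exactly 0); context is
    the weighted sum of hidden states, shape (B, width).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("attention mask selects no steps")
    s = tanh(Hseq @ W_a + b_a)  # (B, T, d_a)
    logits = (s @ v_a) * (1.0 / math.sqrt(d_k))  # (B, T, 1)
    neg = np.where(mask, 0.0, -1e30)[None, :, None]
    logits = logits + Tensor(neg)
    shifted = logits - Tensor(logits.data.max(axis=1, keepdims=True))
    expw = ad.exp(shifted) * Tensor(mask[None, :, None].astype(float))
    weights = expw / expw.sum(axis=1, keepdims=True)  # (B, T, 1)
    return (weights * Hseq).sum(axis=1), weights


def multi_scale_attention(Hseq: Tensor, params: dict, hp: Hyperparameters,
                          window: int) -> Tensor:
    """Three lag-scale modules of ``heads_per_scale`` heads each.

    Head contexts within a scale are concatenated and projected back to the
    hidden width; the per-scale contexts are concatenated, giving a vector
    of 3 x hidden width.
    """
    contexts = []
    for si, (lo, hi) in enumerate(hp.scales):
        mask = scale_mask(window, lo, hi)
        heads = []
        for hj in range(hp.heads_per_scale):
            p = params[f"scale{si}_head{hj}"]
            ctx, _ = attention_head(Hseq, p["W_a"], p["b_a"], p["v_a"], hp.d_a, mask)
            heads.append(ctx)
        fused = concat(heads, axis=1)
        proj = params[f"scale{si}_proj"]
        contexts.append(fused @ proj["W"] + proj["b"])
    return concat(contexts, axis=1)


def group_heads(C: Tensor, params: dict) -> Tensor:
    """Shared ReLU layer followed by independent affine heads per group.

    The heads are stored column-stacked: W_groups is (d_shared, G), b_groups
    (G,), which evaluates all G heads in parallel.
    """
    H_shared = relu(C @ params["W_shared"] + params["b_shared"])
    if params["W_groups"].shape[0] != H_shared.shape[-1]:
        raise ValueError("shared width does not match group head width")
    return H_shared @ params["W_groups"] + params["b_groups"]


def residual_fusion(X: Tensor, y_deep: Tensor, W_residual: Tensor, alpha_raw: Tensor):
    """Convex fusion of the deep and linear pathways.

    Returns (fused, deep_path, residual_path, alpha) where the pathway terms
    are already alpha-weighted: fused = alpha*y_deep + (1-alpha)*X_avg W_r.
    """
    X = ad.as_tensor(X)
    X_avg = X.mean(axis=1)  # (B, D)
    alpha = sigmoid(alpha_raw)
    deep_term = alpha * y_deep
    residual_term = (1.0 - alpha) * (X_avg @ W_residual)
    return deep_term + residual_term, deep_term, residual_term, alpha


def ensemble_predict(models: list, X: np.ndarray) -> np.ndarray:
    """Unweighted mean of member predictions (evaluation mode)."""
    if not models:
        raise ValueError("ensemble requires at least one member")
    preds = [m.predict(X) for m in models]
    return np.mean(preds, axis=0)


# -- batch normalization ---------------------------------------------------


class BatchNorm:
    """1-D batch norm with running statistics for evaluation mode."""

    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xh = (x - mu) / ad.sqrt(var + self.eps)
        else:
            xh = (x - Tensor(self.running_mean)) / ad.sqrt(Tensor(self.running_var + self.eps))
        return xh * self.gamma + self.beta

    def parameters(self) -> list:
        return [self.gamma, self.beta]


# -- the assembled model ---------------------------------------------------


def _uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


@dataclass
class DualPathwayModel:
    """All learnable state plus the forward pass, for one ensemble member."""

    n_features: int
    n_groups: int
    window: int
    hp: Hyperparameters
    seed: int = 0
    params: dict = field(default_factory=dict, repr=False)
    bn: BatchNorm | None = field(default=None, repr=False)

    def __post_init__(self):
        self.hp.validate_scales(self.window)
        if not self.params:
            self._init_params()

    def _init_params(self) -> None:
        rng = np.random.default_rng(self.seed)
        hp = self.hp
        p: dict = {}
        p["W_input"] = Tensor(_uniform(rng, (self.n_features, hp.d_h), self.n_features),
                              requires_grad=True)
        p["b_input"] = Tensor(np.zeros(hp.d_h), requires_grad=True)
        self.bn = BatchNorm(hp.d_h) if hp.batchnorm else None

        self.lstm_layers: list = []
        d_dir = 2 * hp.d_h if hp.bidirectional else hp.d_h
        for li in range(hp.n_lstm_layers):
            d_in = hp.d_h if li == 0 else d_dir
            layer = {}
            directions = ("forward", "backward") if hp.bidirectional else ("forward",)
            for direction in directions:
                w = {}
                fan = hp.d_h + d_in
                for gate in ("f", "i", "C", "o"):
                    w[f"W_{gate}"] = Tensor(_uniform(rng, (fan, hp.d_h), fan), requires_grad=True)
                    bias = np.ones(hp.d_h) if gate == "f" else np.zeros(hp.d_h)
                    w[f"b_{gate}"] = Tensor(bias, requires_grad=True)  # forget bias init 1.0
                layer[direction] = w
                for gate in ("f", "i", "C", "o"):
                    p[f"lstm{li}_{direction}_W_{gate}"] = w[f"W_{gate}"]
                    p[f"lstm{li}_{direction}_b_{gate}"] = w[f"b_{gate}"]
            self.lstm_layers.append(layer)

        self.attn_params: dict = {}
        if hp.use_attention:
            for si in range(len(hp.scales)):
                for hj in range(hp.heads_per_scale):
                    head = {
                        "W_a": Tensor(_uniform(rng, (d_dir, hp.d_a), d_dir), requires_grad=True),
                        "b_a": Tensor(np.zeros(hp.d_a), requires_grad=True),
                        "v_a": Tensor(_uniform(rng, (hp.d_a, 1), hp.d_a), requires_grad=True),
                    }
                    self.attn_params[f"scale{si}_head{hj}"] = head
                    for k, v in head.items():
                        p[f"attn_s{si}h{hj}_{k}"] = v
                fan = hp.heads_per_scale * d_dir
                proj = {"W": Tensor(_uniform(rng, (fan, d_dir), fan), requires_grad=True),
                        "b": Tensor(np.zeros(d_dir), requires_grad=True)}
                self.attn_params[f"scale{si}_proj"] = proj
                p[f"attn_s{si}_proj_W"] = proj["W"]
                p[f"attn_s{si}_proj_b"] = proj["b"]
            d_ctx = len(hp.scales) * d_dir
        else:
            d_ctx = d_dir  # last hidden state feeds the shared layer directly

        self.head_params = {
            "W_shared": Tensor(_uniform(rng, (d_ctx, hp.d_shared), d_ctx), requires_grad=True),
            "b_shared": Tensor(np.zeros(hp.d_shared), requires_grad=True),
            "W_groups": Tensor(_uniform(rng, (hp.d_shared, self.n_groups), hp.d_shared),
                               requires_grad=True),
            "b_groups": Tensor(np.zeros(self.n_groups), requires_grad=True),
        }
        p.update({f"head_{k}": v for k, v in self.head_params.items()})

        p["W_residual"] = Tensor(_uniform(rng, (self.n_features, self.n_groups), self.n_features),
                                 requires_grad=True)
        p["alpha_raw"] = Tensor(np.zeros(()), requires_grad=True)  # alpha starts at 0.5
        self.params = p

    # -- forward -----------------------------------------------------------

    def forward(self, X, training: bool = False, rng: np.random.Generator | None = None,
                return_paths: bool = False):
        X = ad.as_tensor(X)
        if not np.all(np.isfinite(X.data)):
            raise FloatingPointError("non-finite values in model input")
        hp = self.hp
        H = input_projection(X, self.params["W_input"], self.params["b_input"],
                             bn=self.bn, training=training)
        Hseq = bilstm_forward(H, self.lstm_layers, hp.d_h, dropout=hp.dropout,
                              training=training, rng=rng)
        if hp.use_attention:
            C = multi_scale_attention(Hseq, self.attn_params, hp, self.window)
        else:
            C = Hseq[:, self.window - 1, :]  # final hidden state
        y_deep = group_heads(C, self.head_params)
        fused, deep_term, residual_term, alpha = residual_fusion(
            X, y_deep, self.params["W_residual"], self.params["alpha_raw"])
        if return_paths:
            return fused, {"deep": deep_term, "residual": residual_term,
                           "alpha": alpha, "y_deep": y_deep}
        return fused

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X, training=False).data

    def pathway_outputs(self, X: np.ndarray) -> dict:
        """Alpha-weighted pre-fusion pathway outputs (evaluation mode)."""
        _, paths = self.forward(X, training=False, return_paths=True)
        return {"deep": paths["deep"].data, "residual": paths["residual"].data,
                "alpha": float(paths["alpha"].data)}

    @property
    def alpha(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.params["alpha_raw"].data)))

    def set_alpha(self, alpha: float) -> None:
        """Pin the fusion weight (clipped away from exact 0/1 for the logit)."""
        a = min(max(alpha, 1e-12), 1 - 1e-12)
        self.params["alpha_raw"].data = np.asarray(math.log(a / (1.0 - a)))

    # -- parameter bookkeeping ---------------------------------------------

    def parameters(self) -> list:
        out = list(self.params.values())
        if self.bn is not None:
            out += self.bn.parameters()
        return out

    def state_arrays(self) -> dict:
        state = {k: v.data.copy() for k, v in self.params.items()}
        if self.bn is not None:
            state["__bn_gamma"] = self.bn.gamma.data.copy()
            state["__bn_beta"] = self.bn.beta.data.copy()
            state["__bn_mean"] = self.bn.running_mean.copy()
            state["__bn_var"] = self.bn.running_var.copy()
        return state

    def load_state_arrays(self, state: dict) -> None:
        for k, v in self.params.items():
            v.data = state[k].copy()
        if self.bn is not None:
            self.bn.gamma.data = state["__bn_gamma"].copy()
            self.bn.beta.data = state["__bn_beta"].copy()
            self.bn.running_mean = state["__bn_mean"].copy()
            self.bn.running_var = state["__bn_var"].copy()

    def clone(self) -> "DualPathwayModel":
        other = DualPathwayModel(n_features=self.n_features, n_groups=self.n_groups,
                                 window=self.window, hp=copy.deepcopy(self.hp), seed=self.seed)
        other.load_state_arrays(self.state_arrays())
        return other

    # -- gradients w.r.t. the input (for attribution) ----------------------

    def input_gradient(self, x: np.ndarray, output: str | int = "sum") -> tuple:
        """Value and gradient of the chosen output w.r.t. one input window.

        ``output`` is ``"sum"`` (sum over the G group outputs) or a group
        index.  ``x`` has shape (window, n_features).
        """
        X = Tensor(x[None, :, :], requires_grad=True)
        pred = self.forward(X, training=False)
        scalar = pred.sum() if output == "sum" else pred[:, int(output)].sum()
        scalar.backward()
        grad = X.grad[0]
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("non-finite gradient in attribution")
        return float(scalar.data), grad
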