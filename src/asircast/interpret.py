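"""Shapley attribution and architectural contribution analysis.

Three levels: (1) global -- mean |phi| per sex-age group, ranked with
shares; (2) local -- signed per-group contributions for one sample;
(3) component -- the alpha-weighted split between the deep and linear
pathways.  Exact Shapley enumeration (small feature counts) serves as the
oracle for the gradient-based approximation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "exact_shap_small",
    "gradient_shap",
    "ShapExplanation",
    "aggregate_to_groups",
    "global_importance",
    "stratified_importance",
    "local_explanation",
    "component_contribution",
    "ComponentContribution",
    "model_value_and_grad",
]

MAX_EXACT_FEATURES = 12


def exact_shap_small(model_fn, x, x_ref) -> np.ndarray:
    """Exact Shapley values by full subset enumeration.

    ``model_fn`` maps a 1-D feature vector to a scalar; masked-out features
    take their reference value.  Refuses more than 12 features (2^F calls).
    """
    x = np.asarray(x, dtype=float).ravel()
    x_ref = np.asarray(x_ref, dtype=float).ravel()
    F = len(x)
    if F > MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration limited to {MAX_EXACT_FEATURES} features, got {F}")
    cache: dict = {}

    def value(subset: frozenset) -> float:
        if subset not in cache:
            z = x_ref.copy()
            idx = list(subset)
            z[idx] = x[idx]
            cache[subset] = float(model_fn(z))
        return cache[subset]

    phi = np.zeros(F)
    others = list(range(F))
    fact = [math.factorial(i) for i in range(F + 1)]
    for j in range(F):
        rest = [i for i in others if i != j]
        for r in range(F):
            weight = fact[r] * fact[F - r - 1] / fact[F]
            for subset in itertools.combinations(rest, r):
                s = frozenset(subset)
                phi[j] += weight * (value(s | {j}) - value(s))
    return phi


@dataclass
class ShapExplanation:
    """Per-sample attributions with completeness bookkeeping.

    ``phi`` has shape (n_samples, *feature_shape); ``completeness_gap`` is
    |sum phi - (f(x) - f(x_ref))| per sample.
    """

    phi: np.ndarray
    x_ref: np.ndarray
    f_x: np.ndarray
    f_ref: float
    M: int
    completeness_gap: np.ndarray = field(init=False)

    def __post_init__(self):
        totals = self.phi.reshape(self.phi.shape[0], -1).sum(axis=1)
        self.completeness_gap = np.abs(totals - (self.f_x - self.f_ref))


def model_value_and_grad(model, output="sum"):
    """Adapt a :class:`DualPathwayModel` to the attribution interface."""

    def fn(x):
        return model.input_gradient(x, output=output)

    return fn


def gradient_shap(value_and_grad, X, background, M: int = 8, path_steps: int = 50,
                  seed: int = 0, one_point: bool = False) -> ShapExplanation:
    """Gradient-based Shapley approximation with path averaging.

    phi = (x - x_ref) * mean gradient, where x_ref is the background mean
    and the gradient is averaged over M stratified draws of path_steps
    interpolation points on the straight line from x_ref to x (so the
    estimate converges to the path integral and completeness holds to a few
    percent on smooth models).  ``one_point=True`` keeps the literal
    single-gradient-at-x estimate for strict replication; it violates
    completeness on nonlinear models.
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if background.shape[0] == 0:
        raise ValueError("background set must be non-empty")
    if M < 1:
        raise ValueError("need M >= 1 gradient samples")
    rng = np.random.default_rng(seed)
    x_ref = background.mean(axis=0)
    f_ref, _ = value_and_grad(x_ref)

    phis, f_xs = [], []
    for si in range(X.shape[0]):
        x = X[si]
        f_x, grad_at_x = value_and_grad(x)
        if one_point:
            avg_grad = grad_at_x
        else:
            total = np.zeros_like(x)
            count = 0
            for _ in range(M):
                for step in range(path_steps):
                    t = (step + rng.random()) / path_steps  # stratified on (0, 1)
                    point = x_ref + t * (x - x_ref)
                    _, g = value_and_grad(point)
                    total += g
                    count += 1
            avg_grad = total / count
        phis.append((x - x_ref) * avg_grad)
        f_xs.append(f_x)
    return ShapExplanation(phi=np.stack(phis), x_ref=x_ref,
                           f_x=np.asarray(f_xs), f_ref=f_ref,
                           M=M * (1 if one_point else path_steps))


# -- aggregation to sex-age groups -----------------------------------------


def _group_keys(manifest: list) -> list:
    seen = []
    for m in manifest:
        key = (m["sex"], m["age_band"])
        if key not in seen:
            seen.append(key)
    return seen


def aggregate_to_groups(expl: ShapExplanation, manifest: list, signed: bool = False) -> pd.DataFrame:
    """Collapse (time-step x column) attributions to the owning sex-age group.

    Each group owns the 6 feature columns tagged with its (sex, age_band);
    importance sums |phi| over those columns and all window steps, signed
    aggregation (for local views) sums phi itself.
    """
    phi = expl.phi
    if phi.ndim == 2:  # (n, D): no time axis
        phi = phi[:, None, :]
    n, T, D = phi.shape
    if D != len(manifest):
        raise ValueError(f"manifest length {len(manifest)} != feature count {D}")
    keys = _group_keys(manifest)
    rows = np.zeros((n, len(keys)))
    for j, m in enumerate(manifest):
        gi = keys.index((m["sex"], m["age_band"]))
        contribution = phi[:, :, j].sum(axis=1) if signed else np.abs(phi[:, :, j]).sum(axis=1)
        rows[:, gi] += contribution
    out = pd.DataFrame(rows, columns=[f"{s}|{b}" for s, b in keys])
    out.attrs["group_keys"] = keys
    return out


def global_importance(expl: ShapExplanation, manifest: list) -> pd.DataFrame:
    """Mean |phi| per group, ranked descending, with share-of-total."""
    table = aggregate_to_groups(expl, manifest, signed=False)
    keys = table.attrs["group_keys"]
    mean_abs = table.mean(axis=0).to_numpy()
    total = mean_abs.sum()
    out = pd.DataFrame({
        "sex": [k[0] for k in keys],
        "age_band": [k[1] for k in keys],
        "mean_abs_phi": mean_abs,
        "share": mean_abs / total if total > 0 else np.full_like(mean_abs, np.nan),
    })
    out["share_defined"] = total > 0
    return out.sort_values("mean_abs_phi", ascending=False).reset_index(drop=True)


def stratified_importance(expl: ShapExplanation, manifest: list) -> dict:
    """Importance totals per age band and per (sex, band) cell."""
    gi = global_importance(expl, manifest)
    by_cell = gi.pivot_table(index="age_band", columns="sex",
                             values="mean_abs_phi", aggfunc="sum")
    by_age = by_cell.sum(axis=1).rename("total").to_frame()
    by_sex = gi.groupby("sex")["mean_abs_phi"].sum().to_frame("total")
    return {"by_age": by_age, "by_cell": by_cell, "by_sex": by_sex}


def local_explanation(expl: ShapExplanation, manifest: list, sample: int,
                      top_k: int = 10) -> dict:
    """Top-k signed group contributions for one sample plus the residual.

    The sum of the listed phi plus the residual equals f(x) - f(x_ref) up to
    the sample's completeness gap (which is also reported).
    """
    n = expl.phi.shape[0]
    if not 0 <= sample < n:
        raise IndexError(f"sample {sample} out of range [0, {n})")
    signed = aggregate_to_groups(expl, manifest, signed=True)
    keys = signed.attrs["group_keys"]
    values = signed.iloc[sample].to_numpy()
    order = np.argsort(-np.abs(values))
    shown = order[:top_k]
    delta = float(expl.f_x[sample] - expl.f_ref)
    contributions = [{"sex": keys[i][0], "age_band": keys[i][1], "phi": float(values[i])}
                     for i in shown if values[i] != 0.0]
    shown_sum = sum(c["phi"] for c in contributions)
    return {
        "contributions": contributions,
        "residual": delta - shown_sum,
        "f_x": float(expl.f_x[sample]),
        "f_ref": float(expl.f_ref),
        "completeness_gap": float(expl.completeness_gap[sample]),
    }


# -- component contribution ------------------------------------------------


@dataclass
class ComponentContribution:
    deep_mean_abs: float
    residual_mean_abs: float
    alpha: float

    @property
    def deep_fraction(self) -> float:
        total = self.deep_mean_abs + self.residual_mean_abs
        return self.deep_mean_abs / total if total > 0 else math.nan

    @property
    def residual_fraction(self) -> float:
        total = self.deep_mean_abs + self.residual_mean_abs
        return self.residual_mean_abs / total if total > 0 else math.nan


def component_contribution(model, X) -> ComponentContribution:
    """Mean |alpha * y_deep| vs |(1 - alpha) * X_avg W_residual| over X."""
    paths = model.pathway_outputs(np.asarray(X, dtype=float))
    return ComponentContribution(
        deep_mean_abs=float(np.abs(paths["deep"]).mean()),
        residual_mean_abs=float(np.abs(paths["residual"]).mean()),
        alpha=paths["alpha"],
    )
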