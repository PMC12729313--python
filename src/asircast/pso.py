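"""Particle swarm search with linearly decaying inertia.

Positions live in a continuous box even for integer/ordinal dimensions;
decoding rounds to the nearest admissible value (ties upward) only when a
candidate is evaluated, so the velocity/position updates stay exact.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SwarmConfig",
    "Dimension",
    "SearchSpace",
    "ParticleState",
    "inertia_weight",
    "update_particle",
    "optimize",
    "default_search_space",
    "optimize_hyperparameters",
]


@dataclass
class SwarmConfig:
    n_particles: int = 8
    max_iterations: int = 20
    w_max: float = 0.9
    w_min: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    velocity_clamp: float = 0.2  # fraction of each dimension's range
    stagnation_window: int | None = None  # early stop if g_best flat this long
    per_dimension_r: bool = True  # r1/r2 drawn per dimension (per-particle scalar otherwise)
    seed: int = 0

    def __post_init__(self):
        if self.w_min > self.w_max:
            raise ValueError("w_min must not exceed w_max")
        if self.n_particles < 2 or self.max_iterations < 1:
            raise ValueError("need n_particles >= 2 and max_iterations >= 1")


@dataclass
class Dimension:
    """One search dimension; ``values`` lists admissible points for non-continuous kinds."""

    name: str
    kind: str  # "continuous" | "integer" | "ordinal"
    low: float = 0.0
    high: float = 1.0
    values: tuple = ()
    log10: bool = False  # position is log10(value); continuous only

    def __post_init__(self):
        if self.kind not in ("continuous", "integer", "ordinal"):
            raise ValueError(f"unknown dimension kind {self.kind!r}")
        if self.kind != "continuous":
            if len(self.values) < 2:
                raise ValueError(f"dimension {self.name}: need >= 2 admissible values")
            self.values = tuple(sorted(self.values))
            self.low, self.high = float(self.values[0]), float(self.values[-1])
        if not (math.isfinite(self.low) and math.isfinite(self.high)):
            raise ValueError(f"dimension {self.name}: bounds must be finite")

    def decode(self, x: float):
        x = min(max(x, self.low), self.high)
        if self.kind == "continuous":
            return 10.0 ** x if self.log10 else x
        # nearest admissible value, ties toward the larger value (round half up)
        best = self.values[0]
        best_d = abs(x - best)
        for v in self.values[1:]:
            d = abs(x - v)
            if d < best_d or math.isclose(d, best_d):
                best, best_d = v, d
        return int(best) if self.kind == "integer" else best


@dataclass
class SearchSpace:
    dimensions: list

    @property
    def names(self) -> list:
        return [d.name for d in self.dimensions]

    @property
    def lows(self) -> np.ndarray:
        return np.array([d.low for d in self.dimensions])

    @property
    def highs(self) -> np.ndarray:
        return np.array([d.high for d in self.dimensions])

    def decode(self, position: np.ndarray) -> dict:
        return {d.name: d.decode(float(x)) for d, x in zip(self.dimensions, position)}


@dataclass
class ParticleState:
    position: np.ndarray
    velocity: np.ndarray
    p_best: np.ndarray
    p_best_fitness: float = math.inf


def inertia_weight(k: int, cfg: SwarmConfig) -> float:
    """Linear decay w(k) = w_max - (w_max - w_min) * k / K_max."""
    if not 0 <= k <= cfg.max_iterations:
        raise ValueError(f"iteration {k} outside [0, {cfg.max_iterations}]")
    return cfg.w_max - (cfg.w_max - cfg.w_min) * k / cfg.max_iterations


def update_particle(p: ParticleState, g_best: np.ndarray, w: float, cfg: SwarmConfig,
                    space: SearchSpace, rng: np.random.Generator) -> ParticleState:
    """Velocity then position update with clamping.

    v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x); x <- x + v.
    Velocity is clamped to +/- velocity_clamp * range per dimension and the
    position to the box.
    """
    ndim = p.position.shape[0]
    shape = ndim if cfg.per_dimension_r else 1
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    v = (w * p.velocity
         + cfg.c1 * r1 * (p.p_best - p.position)
         + cfg.c2 * r2 * (g_best - p.position))
    v_lim = cfg.velocity_clamp * (space.highs - space.lows)
    v = np.clip(v, -v_lim, v_lim)
    x = np.clip(p.position + v, space.lows, space.highs)
    return ParticleState(position=x, velocity=v, p_best=p.p_best.copy(),
                         p_best_fitness=p.p_best_fitness)


@dataclass
class SwarmResult:
    best_position: np.ndarray
    best_params: dict
    best_fitness: float
    history: list  # per-iteration g_best fitness
    records: list = field(default_factory=list)  # (iteration, particle, fitness, params)
    n_evaluations: int = 0


def optimize(space: SearchSpace, fitness, cfg: SwarmConfig) -> SwarmResult:
    """Run the swarm; ``fitness`` maps a decoded parameter dict to a scalar.

    Non-finite fitness marks the evaluation failed (treated as +inf) and
    the search continues.  The evaluation budget is
    n_particles * (max_iterations + 1) including initialization.
    """
    rng = np.random.default_rng(cfg.seed)
    lows, highs = space.lows, space.highs
    v_lim = cfg.velocity_clamp * (highs - lows)

    def safe_eval(position):
        try:
            value = float(fitness(space.decode(position)))
        except FloatingPointError:
            return math.inf
        return value if math.isfinite(value) else math.inf

    particles = []
    records = []
    g_best = None
    g_best_fitness = math.inf
    n_eval = 0
    for i in range(cfg.n_particles):
        x = rng.uniform(lows, highs)
        v = rng.uniform(-v_lim, v_lim)
        fit_val = safe_eval(x)
        n_eval += 1
        records.append({"iteration": 0, "particle": i, "fitness": fit_val,
                        "params": space.decode(x)})
        particles.append(ParticleState(position=x, velocity=v, p_best=x.copy(),
                                       p_best_fitness=fit_val))
        if fit_val < g_best_fitness:
            g_best_fitness, g_best = fit_val, x.copy()

    history = []
    stagnant = 0
    for k in range(cfg.max_iterations):
        w = inertia_weight(k, cfg)
        improved = False
        for i, p in enumerate(particles):
            p = update_particle(p, g_best, w, cfg, space, rng)
            fit_val = safe_eval(p.position)
            n_eval += 1
            records.append({"iteration": k + 1, "particle": i, "fitness": fit_val,
                            "params": space.decode(p.position)})
            if fit_val < p.p_best_fitness:
                p.p_best = p.position.copy()
                p.p_best_fitness = fit_val
            if fit_val < g_best_fitness:
                g_best_fitness, g_best = fit_val, p.position.copy()
                improved = True
            particles[i] = p
        history.append(g_best_fitness)
        stagnant = 0 if improved else stagnant + 1
        if cfg.stagnation_window is not None and stagnant >= cfg.stagnation_window:
            break
    return SwarmResult(best_position=g_best, best_params=space.decode(g_best),
                       best_fitness=g_best_fitness, history=history,
                       records=records, n_evaluations=n_eval)


# -- hyperparameter search wiring ------------------------------------------


def default_search_space() -> SearchSpace:
    """Bounds containing the tuned optimum (64, 2, 0.15, 0.002, 4)."""
    return SearchSpace(dimensions=[
        Dimension(name="d_h", kind="ordinal", values=(16, 32, 64, 128)),
        Dimension(name="n_lstm_layers", kind="integer", values=(1, 2, 3)),
        Dimension(name="dropout", kind="continuous", low=0.05, high=0.5),
        Dimension(name="learning_rate", kind="continuous",
                  low=math.log10(1e-4), high=math.log10(1e-2), log10=True),
        Dimension(name="heads_per_scale", kind="ordinal", values=(2, 4, 8)),
    ])


def make_validation_fitness(train, base_hp, cfg):
    """Fitness = validation RMSE (standardized scale) of one training run.

    Each candidate trains from a seed derived from its parameter values so
    repeated evaluation of the same point is reproducible.
    """
    from .training import TrainingConfig, train_model  # local import: avoid cycle

    def fitness(params: dict) -> float:
        hp_fields = {**base_hp.__dict__, **{k: v for k, v in params.items()
                                            if k in base_hp.__dict__}}
        hp_fields["d_h"] = int(hp_fields["d_h"])
        if "d_h" in params:
            hp_fields["d_a"] = hp_fields["d_shared"] = None
        hp = type(base_hp)(**hp_fields)
        desc = repr(sorted((k, round(float(v), 10)) for k, v in params.items()))
        token = zlib.crc32(desc.encode())
        run_cfg = TrainingConfig(**{**cfg.__dict__, "seed": (cfg.seed + token) % (2 ** 31)})
        trained = train_model(train, hp, run_cfg)
        return math.sqrt(trained.best_val_loss)

    return fitness


def optimize_hyperparameters(train, base_hp, cfg, swarm_cfg: SwarmConfig,
                             space: SearchSpace | None = None):
    """Swarm-search the architecture knobs; returns (best hp, SwarmResult)."""
    space = space or default_search_space()
    fitness = make_validation_fitness(train, base_hp, cfg)
    result = optimize(space, fitness, swarm_cfg)
    hp_fields = {**base_hp.__dict__, **{k: v for k, v in result.best_params.items()
                                        if k in base_hp.__dict__}}
    hp_fields["d_h"] = int(hp_fields["d_h"])
    hp_fields["d_a"] = hp_fields["d_shared"] = None
    best_hp = replace(base_hp, **{k: v for k, v in hp_fields.items()
                                  if k in base_hp.__dict__})
    return best_hp, result
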