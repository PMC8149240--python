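"""Krill herd optimization for binary feature selection.

Each krill's velocity is the three-term Lagrangian sum
``dx/dt = N_i + F_i + RD_i`` — motion induced by neighbours, foraging
toward a fitness-weighted food centroid, and decaying random diffusion.
Objectives are minimized as ``1 - accuracy``; all neighbour and food
effects use normalized objective differences so the update is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ClinicalDataset
from .fitness import FeatureMask, FitnessValue, beats, decode_position

__all__ = ["Krill", "KHConfig", "induced_motion", "foraging_motion",
           "compute_food", "random_diffusion", "select_features_kh"]

EPS = 1e-12


@dataclass
class Krill:
    position: np.ndarray
    induced: np.ndarray
    foraging: np.ndarray
    fitness: FitnessValue | None = None
    best_position: np.ndarray | None = None
    best_fitness: FitnessValue | None = None

    @property
    def objective(self) -> float:
        return self.fitness.objective


@dataclass(frozen=True)
class KHConfig:
    """Speeds and weights of the three motion terms.

    ``V_f`` caps foraging speed, ``N_max`` caps induced speed and
    ``RD_max`` caps diffusion (its stated admissible band is
    [0.002, 0.01]); ``w_n``/``w_f`` are the inertia weights and ``C_t``
    scales the position step.
    """

    V_f: float = 0.02
    RD_max: float = 0.005
    N_max: float = 0.01
    w_n: float = 0.5
    w_f: float = 0.5
    C_t: float = 0.5
    N: int = 20
    iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.V_f, self.RD_max, self.N_max) < 0:
            raise ValueError("speed parameters must be >= 0")
        if self.RD_max != 0 and not (0.002 <= self.RD_max <= 0.01):
            raise ValueError("RD_max must lie in [0.002, 0.01]")
        if not (0.0 < self.w_n < 1.0 and 0.0 < self.w_f < 1.0):
            raise ValueError("inertia weights must lie in (0, 1)")
        if not (0.0 <= self.C_t <= 2.0):
            raise ValueError("C_t must lie in [0, 2]")


def _k_hat(k_i: float, k_j: float, k_worst: float, k_best: float) -> float:
    """Normalized objective difference: positive when j is better than i."""
    return (k_i - k_j) / (k_worst - k_best + EPS)


def _x_hat(x_from: np.ndarray, x_to: np.ndarray) -> np.ndarray:
    d = x_to - x_from
    return d / (np.linalg.norm(d) + EPS)


def sensing_distance(krill: Krill, herd: list[Krill]) -> float:
    """Mean distance to the herd scaled by 1/5 — the neighbourhood radius."""
    dists = [np.linalg.norm(krill.position - other.position) for other in herd]
    return sum(dists) / (5.0 * len(herd))


def induced_motion(krill: Krill, herd: list[Krill], best: Krill, cfg: KHConfig,
                   iteration: int = 0) -> np.ndarray:
    """N_new = N_max * (alpha_local + alpha_target) + w_n * N_old."""
    objs = [k.objective for k in herd]
    k_best, k_worst = min(objs), max(objs)

    alpha = np.zeros_like(krill.position)
    ds = sensing_distance(krill, herd)
    for other in herd:
        if other is krill:
            continue
        dist = np.linalg.norm(krill.position - other.position)
        if dist < ds:
            alpha += _k_hat(krill.objective, other.objective, k_worst, k_best) \
                * _x_hat(krill.position, other.position)

    # exploitative pull toward the best krill, strengthening over time
    frac = iteration / max(cfg.iterations, 1)
    c_best = 2.0 * (frac + EPS)
    alpha += c_best * _k_hat(krill.objective, best.objective, k_worst, k_best) \
        * _x_hat(krill.position, best.position)
    return cfg.N_max * alpha + cfg.w_n * krill.induced


def compute_food(herd: list[Krill]) -> np.ndarray:
    """Objective-weighted centroid: x_food = sum(x_i/K_i) / sum(1/K_i)."""
    if not herd:
        raise ValueError("empty herd")
    weights = np.array([1.0 / max(k.objective, EPS) for k in herd])
    positions = np.stack([k.position for k in herd])
    return (weights[:, None] * positions).sum(axis=0) / weights.sum()


def foraging_motion(krill: Krill, food_position: np.ndarray, food_objective: float,
                    herd: list[Krill], cfg: KHConfig, iteration: int = 0) -> np.ndarray:
    """F_new = V_f * (beta_food + beta_best) + w_f * F_old."""
    objs = [k.objective for k in herd]
    k_best, k_worst = min(objs), max(objs)
    frac = iteration / max(cfg.iterations, 1)

    c_food = 2.0 * (1.0 - frac)
    beta = c_food * _k_hat(krill.objective, food_objective, k_worst, k_best) \
        * _x_hat(krill.position, food_position)
    if krill.best_position is not None:
        beta += _k_hat(krill.objective, krill.best_fitness.objective, k_worst, k_best) \
            * _x_hat(krill.position, krill.best_position)
    return cfg.V_f * beta + cfg.w_f * krill.foraging


def random_diffusion(cfg: KHConfig, iteration: int, rng: np.random.Generator,
                     m: int | None = None, iterations: int | None = None) -> np.ndarray:
    """RD = RD_max * (1 - t/T) * delta, delta ~ Uniform(-1, 1) per dimension."""
    total = cfg.iterations if iterations is None else iterations
    size = m if m is not None else 1
    delta = rng.uniform(-1.0, 1.0, size=size)
    return cfg.RD_max * (1.0 - iteration / max(total, 1)) * delta


def select_features_kh(train: ClinicalDataset, cfg: KHConfig,
                       fitness_fn) -> tuple[FeatureMask, FitnessValue, list[float]]:
    """Run the herd and return the elitist best mask with its trace.

    Position step per iteration: dx = Dt * (N + F + RD) with
    Dt = C_t * m for the unit box; positions are clamped to [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    m = train.n_features
    herd = [Krill(position=rng.uniform(size=m), induced=np.zeros(m),
                  foraging=np.zeros(m)) for _ in range(cfg.N)]
    for k in herd:
        k.fitness = fitness_fn(decode_position(k.position))
        k.best_position = k.position.copy()
        k.best_fitness = k.fitness

    best_mask, best_fit = _best_of(herd)
    trace: list[float] = []
    dt = cfg.C_t * m

    for it in range(cfg.iterations):
        best_krill = min(herd, key=lambda k: (k.objective, k.fitness.mask_cardinality))
        food = compute_food(herd)
        food_fit = fitness_fn(decode_position(np.clip(food, 0.0, 1.0)))
        new_induced, new_foraging, new_positions = [], [], []
        for k in herd:
            n_i = induced_motion(k, herd, best_krill, cfg, iteration=it)
            f_i = foraging_motion(k, food, food_fit.objective, herd, cfg, iteration=it)
            rd_i = random_diffusion(cfg, it, rng, m=m)
            new_induced.append(n_i)
            new_foraging.append(f_i)
            new_positions.append(np.clip(k.position + dt * (n_i + f_i + rd_i), 0.0, 1.0))
        for k, n_i, f_i, pos in zip(herd, new_induced, new_foraging, new_positions):
            k.induced, k.foraging, k.position = n_i, f_i, pos
            k.fitness = fitness_fn(decode_position(pos))
            if beats(k.fitness, k.best_fitness):
                k.best_fitness = k.fitness
                k.best_position = pos.copy()
        cand_mask, cand_fit = _best_of(herd)
        if beats(cand_fit, best_fit):
            best_mask, best_fit = cand_mask, cand_fit
        trace.append(best_fit.accuracy)
    return best_mask, best_fit, trace


def _best_of(herd: list[Krill]) -> tuple[FeatureMask, FitnessValue]:
    best = herd[0]
    for k in herd[1:]:
        if beats(k.fitness, best.fitness):
            best = k
    return decode_position(best.position), best.fitness
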