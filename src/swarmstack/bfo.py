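"""Bacterial foraging optimization for binary feature selection.

Bacteria climb the (minimized) objective ``1 - accuracy`` plus an optional
cell-to-cell swarming potential through four nested operators: chemotaxis
(tumble along a random unit direction, then swim while improving),
swarming, reproduction (the healthier half splits, the rest die), and
elimination-dispersal (random relocation with probability ``P_ed``).
Reported fitness is always pure SVM accuracy, never the swarmed objective,
so results are comparable across selectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import ClinicalDataset
from .fitness import FeatureMask, FitnessValue, beats, decode_position

__all__ = ["Bacterium", "BFOConfig", "tumble_direction", "chemotaxis_step",
           "swarming_term", "reproduction", "elimination_dispersal",
           "select_features_bfo"]


@dataclass
class Bacterium:
    position: np.ndarray
    health: float = 0.0
    J_last: float = np.inf
    fitness: FitnessValue | None = None


@dataclass(frozen=True)
class BFOConfig:
    """Chemotaxis / reproduction / dispersal schedule and swarming weights."""

    S: int = 20
    S_r: int | None = None          # defaults to S // 2
    N_c: int = 10
    N_s: int = 4
    N_re: int = 4
    N_ed: int = 2
    P_ed: float = 0.25
    L: float = 0.1                  # chemotactic step length
    d_attract: float = 0.1
    w_attract: float = 0.2
    h_repel: float = 0.1
    w_repel: float = 10.0
    swarming: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.P_ed <= 1.0):
            raise ValueError("P_ed must lie in [0, 1]")
        if self.N_s < 0:
            raise ValueError("N_s must be >= 0")
        if self.survivors * 2 != self.S and self.S_r is None:
            raise ValueError("S must be even when S_r defaults to S/2")

    @property
    def survivors(self) -> int:
        return self.S // 2 if self.S_r is None else self.S_r


def tumble_direction(p: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-component random vector normalized to unit Euclidean length."""
    if p < 1:
        raise ValueError("dimension must be >= 1")
    while True:
        delta = rng.uniform(-1.0, 1.0, size=p)
        norm = np.linalg.norm(delta)
        if norm > 0:
            return delta / norm


def swarming_term(theta: np.ndarray, herd: list[Bacterium], cfg: BFOConfig) -> float:
    """J_cc(theta): Gaussian attraction minus sharper Gaussian repulsion."""
    if not herd:
        raise ValueError("empty herd")
    sq = np.array([float(np.sum((theta - b.position) ** 2)) for b in herd])
    attract = -cfg.d_attract * np.exp(-cfg.w_attract * sq)
    repel = cfg.h_repel * np.exp(-cfg.w_repel * sq)
    return float(attract.sum() + repel.sum())


def _objective(position: np.ndarray, herd: list[Bacterium], cfg: BFOConfig,
               fitness_fn) -> tuple[float, FitnessValue]:
    fit = fitness_fn(decode_position(position))
    obj = fit.objective
    if cfg.swarming:
        obj += swarming_term(position, herd, cfg)
    return obj, fit


def chemotaxis_step(b: Bacterium, herd: list[Bacterium], cfg: BFOConfig,
                    fitness_fn, rng: np.random.Generator) -> Bacterium:
    """One tumble followed by up to N_s swims along the improving direction.

    ``J_last`` tracks the best objective in this chemotactic step; health
    accumulates every evaluated objective (lower total = healthier).
    """
    direction = tumble_direction(b.position.size, rng)
    position = np.clip(b.position + cfg.L * direction, 0.0, 1.0)
    obj, fit = _objective(position, herd, cfg, fitness_fn)
    health = b.health + obj
    j_last = b.J_last
    swims = 0
    while obj < j_last and swims < cfg.N_s:
        j_last = obj
        nxt = np.clip(position + cfg.L * direction, 0.0, 1.0)
        obj, nfit = _objective(nxt, herd, cfg, fitness_fn)
        health += obj
        swims += 1
        if obj < j_last:
            position, fit = nxt, nfit
    return replace(b, position=position, health=health,
                   J_last=min(j_last, obj), fitness=fit)


def reproduction(herd: list[Bacterium], cfg: BFOConfig) -> list[Bacterium]:
    """The healthiest S_r bacteria each split in two; the rest die."""
    order = sorted(range(len(herd)), key=lambda i: herd[i].health)
    out: list[Bacterium] = []
    for i in order[: cfg.survivors]:
        b = herd[i]
        for _ in range(2):
            out.append(Bacterium(position=b.position.copy(), health=0.0,
                                 J_last=np.inf, fitness=b.fitness))
    # conserve population size when S_r != S/2
    while len(out) < len(herd):
        b = herd[order[0]]
        out.append(Bacterium(position=b.position.copy(), fitness=b.fitness))
    return out[: len(herd)]


def elimination_dispersal(herd: list[Bacterium], cfg: BFOConfig,
                          rng: np.random.Generator) -> list[Bacterium]:
    """Relocate each bacterium to a uniform random position w.p. P_ed."""
    out = []
    for b in herd:
        if rng.uniform() < cfg.P_ed:
            out.append(Bacterium(position=rng.uniform(size=b.position.size)))
        else:
            out.append(b)
    return out


def select_features_bfo(train: ClinicalDataset, cfg: BFOConfig,
                        fitness_fn) -> tuple[FeatureMask, FitnessValue, list[float]]:
    """Triple loop z (dispersal) / y (reproduction) / x (chemotaxis)."""
    rng = np.random.default_rng(cfg.seed)
    m = train.n_features
    herd = [Bacterium(position=rng.uniform(size=m)) for _ in range(cfg.S)]

    best_mask: FeatureMask | None = None
    best_fit: FitnessValue | None = None
    trace: list[float] = []

    def consider(b: Bacterium) -> None:
        nonlocal best_mask, best_fit
        if best_fit is None or beats(b.fitness, best_fit):
            best_fit = b.fitness
            best_mask = decode_position(b.position)

    for z in range(cfg.N_ed):
        for y in range(cfg.N_re):
            for b in herd:
                obj, fit = _objective(b.position, herd, cfg, fitness_fn)
                b.J_last = obj
                b.health = 0.0
                b.fitness = fit
                consider(b)
            for x in range(cfg.N_c):
                for i, b in enumerate(herd):
                    herd[i] = chemotaxis_step(b, herd, cfg, fitness_fn, rng)
                    consider(herd[i])
                trace.append(best_fit.accuracy)
            herd = reproduction(herd, cfg)
        herd = elimination_dispersal(herd, cfg, rng)
        for b in herd:
            if b.fitness is None:
                b.fitness = fitness_fn(decode_position(b.position))
                consider(b)
    return best_mask, best_fit, trace
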