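"""Cat swarm optimization for binary feature selection.

Cats carry a continuous position in the unit box that is thresholded into
a feature mask (see :func:`swarmstack.fitness.decode_position`).  Each
iteration a random ``round(MR * N)`` of the population trace (velocity
move toward the global best) while the rest seek (perturb-and-select
local search over a small memory pool).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataio import ClinicalDataset, round_half_up
from .fitness import FeatureMask, FitnessValue, beats, decode_position

__all__ = ["Cat", "CSOConfig", "decode_mask", "seeking_mode", "tracing_mode",
           "select_features_cso"]

decode_mask = decode_position


@dataclass
class Cat:
    position: np.ndarray
    velocity: np.ndarray
    spc_flag: bool = False
    fitness: FitnessValue | None = None


@dataclass(frozen=True)
class CSOConfig:
    """Seeking/tracing parameters.

    ``SMP`` candidate copies per seeking cat, each perturbing a random
    ``CDC`` fraction of dimensions by +/- ``SRD``; tracing cats move with
    velocity gain ``c`` toward the best cat, capped at ``v_max``.
    """

    N: int = 20
    MR: float = 0.3
    SMP: int = 5
    SRD: float = 0.2
    CDC: float = 0.8
    c: float = 2.0
    v_max: float = 1.0
    iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2 or self.SMP < 1:
            raise ValueError("need N >= 2 and SMP >= 1")
        if not (0.0 < self.MR < 1.0):
            raise ValueError("MR must lie in (0, 1)")
        if self.SRD < 0:
            raise ValueError("SRD must be >= 0")


def seeking_mode(cat: Cat, cfg: CSOConfig, fitness_fn, rng: np.random.Generator) -> Cat:
    """Local search: spawn SMP candidates, keep one by fitness-weighted draw.

    With ``spc_flag`` the unmodified current position occupies one memory
    slot.  Candidate probabilities are proportional to relative fitness
    (accuracy), falling back to uniform when all candidates tie.
    """
    m = cat.position.size
    n_mut = cfg.SMP - 1 if cat.spc_flag else cfg.SMP
    candidates = [cat.position.copy()] if cat.spc_flag else []
    n_change = max(1, round_half_up(cfg.CDC * m))
    for _ in range(n_mut):
        pos = cat.position.copy()
        dims = rng.choice(m, size=min(n_change, m), replace=False)
        signs = rng.choice([-1.0, 1.0], size=dims.size)
        pos[dims] = np.clip(pos[dims] + signs * cfg.SRD, 0.0, 1.0)
        candidates.append(pos)

    values = [fitness_fn(decode_position(p)) for p in candidates]
    accs = np.array([v.accuracy for v in values])
    if np.ptp(accs) == 0:
        probs = np.full(len(candidates), 1.0 / len(candidates))
    else:
        weights = (accs - accs.min()) / np.ptp(accs)
        probs = weights / weights.sum()
    pick = rng.choice(len(candidates), p=probs)
    return replace(cat, position=candidates[pick], fitness=values[pick])


def tracing_mode(cat: Cat, global_best: Cat, cfg: CSOConfig,
                 rng: np.random.Generator) -> Cat:
    """Velocity move toward the global best, clamped to +/- v_max and [0,1]."""
    r = rng.uniform(size=cat.position.size)
    velocity = cat.velocity + r * cfg.c * (global_best.position - cat.position)
    velocity = np.clip(velocity, -cfg.v_max, cfg.v_max)
    position = np.clip(cat.position + velocity, 0.0, 1.0)
    return replace(cat, position=position, velocity=velocity)


def select_features_cso(train: ClinicalDataset, cfg: CSOConfig,
                        fitness_fn) -> tuple[FeatureMask, FitnessValue, list[float]]:
    """Run the full swarm and return the elitist best mask with its trace."""
    rng = np.random.default_rng(cfg.seed)
    m = train.n_features
    cats = [
        Cat(
            position=rng.uniform(size=m),
            velocity=rng.uniform(-cfg.v_max, cfg.v_max, size=m),
        )
        for _ in range(cfg.N)
    ]
    for cat in cats:
        cat.fitness = fitness_fn(decode_position(cat.position))

    best_mask, best_fit = _best_of(cats, fitness_fn)
    trace: list[float] = []
    n_tracing = min(cfg.N, max(1, round_half_up(cfg.MR * cfg.N)))

    for _ in range(cfg.iterations):
        tracing_idx = set(rng.choice(cfg.N, size=n_tracing, replace=False).tolist())
        best_cat = Cat(position=_position_of(best_mask, cats, best_fit),
                       velocity=np.zeros(m), fitness=best_fit)
        for i, cat in enumerate(cats):
            if i in tracing_idx:
                moved = tracing_mode(cat, best_cat, cfg, rng)
                moved.fitness = fitness_fn(decode_position(moved.position))
                cats[i] = moved
            else:
                cat.spc_flag = bool(rng.uniform() < 0.5)
                cats[i] = seeking_mode(cat, cfg, fitness_fn, rng)
        cand_mask, cand_fit = _best_of(cats, fitness_fn)
        if beats(cand_fit, best_fit):
            best_mask, best_fit = cand_mask, cand_fit
        trace.append(best_fit.accuracy)
    return best_mask, best_fit, trace


def _best_of(cats: list[Cat], fitness_fn) -> tuple[FeatureMask, FitnessValue]:
    best_cat = cats[0]
    for cat in cats[1:]:
        if beats(cat.fitness, best_cat.fitness):
            best_cat = cat
    mask = decode_position(best_cat.position)
    return mask, best_cat.fitness


def _position_of(mask: FeatureMask, cats: list[Cat], fit: FitnessValue) -> np.ndarray:
    # prefer the live cat currently decoding to the best mask; otherwise the
    # mask itself is a valid position (bits are in {0,1} and decode to itself)
    for cat in cats:
        if decode_position(cat.position).bits == mask.bits and cat.fitness == fit:
            return cat.position.copy()
    return np.asarray(mask.bits, dtype=float)
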