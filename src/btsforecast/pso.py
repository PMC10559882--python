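"""Bounded particle-swarm optimizer for mixed integer/continuous spaces.

Classical inertia-weight PSO with cognitive and social terms.  Dimensions
flagged in ``integer_mask`` stay continuous inside the swarm but are rounded
at evaluation time, which keeps the dynamics smooth for mixed spaces such as
ARMA orders alongside a fractional differencing exponent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyperparameters.

    Defaults use the constriction-equivalent constants w=0.729,
    c1=c2=1.49445 widely recommended for the classical algorithm.
    """

    swarm_size: int = 20
    iterations: int = 30
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.5  # fraction of each dimension's range
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.inertia <= 1:
            raise ValueError("inertia must be in (0, 1]")
        if self.cognitive <= 0 or self.social <= 0:
            raise ValueError("cognitive and social constants must be positive")


@dataclass
class PsoResult:
    best_position: np.ndarray
    best_fitness: float
    history: list[float] = field(default_factory=list)


def _evaluate(objective, pos: np.ndarray, integer_mask: np.ndarray) -> float:
    x = pos.copy()
    x[integer_mask] = np.round(x[integer_mask])
    try:
        f = float(objective(x))
    except Exception as exc:  # a failing candidate must not kill the swarm
        logger.debug("objective raised at %s: %s", x, exc)
        return np.inf
    if not np.isfinite(f):
        logger.debug("non-finite fitness at %s", x)
        return np.inf
    return f


def pso_optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    integer_mask: Sequence[bool] | None = None,
    config: PsoConfig | None = None,
    initial_positions: Sequence[Sequence[float]] | None = None,
) -> PsoResult:
    """Minimize ``objective`` over a box; lower fitness is better.

    ``initial_positions`` may seed part of the swarm (e.g. with a known
    default configuration); remaining particles are drawn uniformly in the
    box.  The returned history holds the global best per iteration and is
    non-increasing.  Fully reproducible under the config seed.
    """
    cfg = config or PsoConfig()
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()) or (hi <= lo).any():
        raise ValueError("bounds must be finite with hi > lo")
    dim = lo.size
    imask = np.zeros(dim, dtype=bool) if integer_mask is None else np.asarray(integer_mask, dtype=bool)

    rng = np.random.default_rng(cfg.seed)
    pos = rng.uniform(lo, hi, size=(cfg.swarm_size, dim))
    if initial_positions is not None:
        seeds = np.clip(np.asarray(initial_positions, dtype=float), lo, hi)
        pos[: len(seeds)] = seeds
    vmax = cfg.velocity_clamp * (hi - lo)
    vel = rng.uniform(-vmax, vmax, size=(cfg.swarm_size, dim))

    pbest = pos.copy()
    pbest_f = np.array([_evaluate(objective, p, imask) for p in pos])
    g = int(np.argmin(pbest_f))
    gbest, gbest_f = pbest[g].copy(), float(pbest_f[g])

    history: list[float] = []
    for it in range(cfg.iterations):
        r1 = rng.random((cfg.swarm_size, dim))
        r2 = rng.random((cfg.swarm_size, dim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            f = _evaluate(objective, pos[i], imask)
            if f < pbest_f[i]:
                pbest[i], pbest_f[i] = pos[i].copy(), f
                if f < gbest_f:
                    gbest, gbest_f = pos[i].copy(), f
        history.append(gbest_f)
        logger.debug("pso iteration %d best fitness %.6g", it, gbest_f)

    best = gbest.copy()
    best[imask] = np.round(best[imask])
    return PsoResult(best_position=best, best_fitness=gbest_f, history=history)
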