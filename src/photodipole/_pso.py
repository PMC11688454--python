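"""Seeded particle-swarm optimizer with simplex polish.

Vectorised constriction-type PSO (inertia 0.72, cognitive/social 1.49 --
the standard Clerc-Kennedy settings) over box bounds with reflecting
walls, followed by a deterministic Nelder-Mead polish of the swarm best.
The objective is called on a ``(n_particles, n_params)`` array and must
return a length-``n_particles`` vector, which keeps per-iteration cost at
a single vectorised model evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize

__all__ = ["PSOConfig", "PSOResult", "pso_minimize"]


@dataclass(frozen=True)
class PSOConfig:
    swarm: int = 50
    iters: int = 500
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    seed: int | None = None
    # stop early when the swarm best has not improved by rel_tol for `patience` iters
    patience: int = 80
    rel_tol: float = 1e-10
    polish: bool = True


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    n_iter: int
    best_history: np.ndarray      # swarm-best objective per iteration (nonincreasing)
    polished: bool


def _reflect(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    return lo + np.where(y > span, 2 * span - y, y)


def pso_minimize(fun: Callable[[np.ndarray], np.ndarray],
                 bounds: list[tuple[float, float]],
                 config: PSOConfig = PSOConfig(),
                 x0: np.ndarray | None = None) -> PSOResult:
    """Minimise ``fun`` over box ``bounds``.

    ``fun`` maps a ``(m, d)`` parameter block to ``m`` objective values.
    ``x0``, if given, seeds one particle (the rest are uniform in the box).
    The returned best is never worse than any initial particle, and the
    polish step is only accepted if it does not increase the objective.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)) or np.any(hi <= lo):
        raise ValueError("bounds must be finite with high > low")
    d = lo.size
    rng = np.random.default_rng(config.seed)

    x = lo + (hi - lo) * rng.random((config.swarm, d))
    if x0 is not None:
        x[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    v = 0.1 * (hi - lo) * (rng.random((config.swarm, d)) - 0.5)

    f = np.asarray(fun(x), dtype=float)
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])

    history = [gbest_f]
    stale = 0
    it = 0
    for it in range(1, config.iters + 1):
        r1 = rng.random((config.swarm, d))
        r2 = rng.random((config.swarm, d))
        v = (config.inertia * v
             + config.c1 * r1 * (pbest_x - x)
             + config.c2 * r2 * (gbest_x - x))
        x = _reflect(x + v, lo, hi)
        f = np.asarray(fun(x), dtype=float)

        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            rel_impr = (gbest_f - pbest_f[g]) / max(abs(gbest_f), 1e-300)
            stale = 0 if rel_impr > config.rel_tol else stale + 1
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        else:
            stale += 1
        history.append(gbest_f)
        if stale >= config.patience:
            break

    polished = False
    if config.polish:
        # evaluate clipped into the box so the simplex cannot step outside
        res = minimize(lambda p: float(fun(np.clip(p, lo, hi)[None, :])[0]),
                       gbest_x, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 2000})
        if res.fun <= gbest_f:
            x_clip = np.clip(res.x, lo, hi)
            f_clip = float(fun(x_clip[None, :])[0])
            if f_clip <= gbest_f:       # clipping back into the box could undo the gain
                gbest_x, gbest_f = x_clip, f_clip
                polished = True

    return PSOResult(x=gbest_x, fun=gbest_f, n_iter=it,
                     best_history=np.asarray(history), polished=polished)
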