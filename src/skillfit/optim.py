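"""Self-contained global-best particle swarm optimizer.

Both fitting stages of the package (sum-of-squared-error curve fits and
negative-summed-log-likelihood diffusion fits) minimise non-convex objectives
over a box.  A global-best PSO with the standard constriction coefficients is
used, optionally followed by a Nelder-Mead polish of the swarm optimum.

Objectives may be *batched*: a callable that maps an ``(n_particles, ndim)``
array to ``(n_particles,)`` objective values.  All likelihood code in this
package is written in that form so that a whole swarm is evaluated in one
vectorised pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as _sciopt

__all__ = ["OptimizerConfig", "PSOResult", "minimize_pso"]


@dataclass
class OptimizerConfig:
    """Settings for the particle-swarm minimiser.

    Parameters
    ----------
    swarm_size : int
        Number of particles.
    iterations : int
        PSO iterations per restart.
    n_restarts : int
        Independent restarts; the best objective over restarts is returned.
    inertia, cognitive, social : float
        Velocity-update coefficients (Clerc-Kennedy constriction defaults).
    polish : bool
        Run a bounded Nelder-Mead refinement from the swarm optimum.
    stall_iterations : int
        Stop a restart early when the swarm optimum has not improved by
        ``stall_tol`` for this many consecutive iterations (0 disables).
    seed : int or None
        Seed for particle initialisation; restarts use spawned streams.
    """

    swarm_size: int = 40
    iterations: int = 300
    n_restarts: int = 5
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    polish: bool = True
    polish_maxfev_per_dim: int = 80
    stall_iterations: int = 0
    stall_tol: float = 1e-7
    seed: int | None = None

    def validate(self, ndim: int) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1 or self.n_restarts < 1:
            raise ValueError("iterations and n_restarts must be >= 1")


@dataclass
class PSOResult:
    x: np.ndarray
    fun: float
    nit: int
    n_restarts: int
    restart_funs: list = field(default_factory=list)
    restart_xs: list = field(default_factory=list)


def _as_batch(func, batched: bool):
    if batched:
        return func
    return lambda X: np.array([func(x) for x in X], dtype=float)


def minimize_pso(
    func,
    bounds,
    config: OptimizerConfig | None = None,
    *,
    batched: bool = True,
    seed: int | None = None,
    x0: np.ndarray | None = None,
) -> PSOResult:
    """Minimise ``func`` over the box ``bounds``.

    Parameters
    ----------
    func : callable
        Objective.  If ``batched`` (default) it receives an
        ``(n_particles, ndim)`` array and returns ``(n_particles,)`` values.
    bounds : sequence of (low, high)
        Finite box constraints, one pair per dimension.
    config : OptimizerConfig
    batched : bool
        Whether ``func`` is vectorised over particles.
    seed : int, optional
        Overrides ``config.seed``.
    x0 : ndarray, optional
        One point, or an (m, ndim) array of points, injected into the
        initial swarm of every restart (useful to warm-start nested models
        from a parent fit or from method-of-moments estimates).
    """
    config = config or OptimizerConfig()
    lo, hi = np.asarray(bounds, dtype=float).T
    if not (np.isfinite(lo).all() and np.isfinite(hi).all()):
        raise ValueError("bounds must be finite")
    if np.any(lo > hi):
        raise ValueError("bounds must be ordered (low <= high)")
    ndim = lo.size
    config.validate(ndim)
    f = _as_batch(func, batched)

    root_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(root_seed)
    streams = ss.spawn(config.n_restarts)

    span = hi - lo
    best_x, best_f = None, np.inf
    restart_funs, restart_xs = [], []
    for r, child in enumerate(streams):
        rng = np.random.default_rng(child)
        X = lo + span * rng.random((config.swarm_size, ndim))
        if x0 is not None:
            starts = np.atleast_2d(np.asarray(x0, dtype=float))
            m = min(starts.shape[0], config.swarm_size)
            X[:m] = np.clip(starts[:m], lo, hi)
        V = span * (rng.random((config.swarm_size, ndim)) - 0.5)
        pbest_x = X.copy()
        pbest_f = f(X)
        g = int(np.argmin(pbest_f))
        gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

        stall = 0
        for _ in range(config.iterations):
            r1 = rng.random((config.swarm_size, ndim))
            r2 = rng.random((config.swarm_size, ndim))
            V = (
                config.inertia * V
                + config.cognitive * r1 * (pbest_x - X)
                + config.social * r2 * (gbest_x - X)
            )
            X = X + V
            # absorb at the box: clip and kill the offending velocity component
            out = (X < lo) | (X > hi)
            np.clip(X, lo, hi, out=X)
            V[out] = 0.0
            fx = f(X)
            improved = fx < pbest_f
            pbest_x[improved] = X[improved]
            pbest_f[improved] = fx[improved]
            g = int(np.argmin(pbest_f))
            if pbest_f[g] < gbest_f - config.stall_tol:
                stall = 0
            else:
                stall += 1
            if pbest_f[g] < gbest_f:
                gbest_f = float(pbest_f[g])
                gbest_x = pbest_x[g].copy()
            if config.stall_iterations and stall >= config.stall_iterations:
                break

        if config.polish:
            res = _sciopt.minimize(
                lambda x: float(f(x[None, :])[0]),
                gbest_x,
                method="Nelder-Mead",
                bounds=list(zip(lo, hi)),
                options={
                    "maxiter": config.polish_maxfev_per_dim * ndim,
                    "maxfev": config.polish_maxfev_per_dim * ndim,
                    "xatol": 1e-5,
                    "fatol": 1e-7,
                },
            )
            if np.isfinite(res.fun) and res.fun < gbest_f:
                gbest_f, gbest_x = float(res.fun), np.clip(res.x, lo, hi)

        restart_funs.append(gbest_f)
        restart_xs.append(gbest_x.copy())
        if gbest_f < best_f:
            best_f, best_x = gbest_f, gbest_x

    return PSOResult(
        x=best_x,
        fun=best_f,
        nit=config.iterations,
        n_restarts=config.n_restarts,
        restart_funs=restart_funs,
        restart_xs=restart_xs,
    )
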