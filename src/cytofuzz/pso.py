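"""Particle swarm optimization and membership-function tuning.

Canonical global-best PSO with inertia ``w`` and cognitive/social weights
``c1``/``c2`` (constriction-equivalent defaults w = 0.729,
c1 = c2 = 1.49445):

    v_i <- w v_i + c1 r1 * (pbest_i - x_i) + c2 r2 * (gbest - x_i)
    x_i <- clamp(x_i + v_i, bounds)

Positions are clamped to the box, velocities are not.  The tuner searches the
16 membership-function parameters of a Mamdani system (rule consequents stay
fixed) to minimize the RMSE between predictions and observed growth rates; a
candidate violating the parameter constraints scores a large penalty instead
of raising, so the swarm can traverse freely.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .fuzzy import MamdaniFIS

PENALTY = 1.0e6


@dataclass
class PSOConfig:
    swarm_size: int = 30
    iterations: int = 200
    inertia: float = 0.729
    cognitive: float = 1.49445
    social: float = 1.49445
    seed: int = 0

    def validate(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class PSOResult:
    best_x: np.ndarray
    best_f: float
    trace: np.ndarray  # gbest value after each iteration (non-increasing)


def pso_minimize(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    config: PSOConfig | None = None,
    x0: np.ndarray | None = None,
) -> PSOResult:
    """Minimize ``objective`` over a box; deterministic under ``config.seed``.

    ``x0``, when given, seeds particle 0 (a warm start); the rest of the
    swarm initializes uniformly in the box.
    """
    config = config or PSOConfig()
    config.validate()
    lo = np.asarray([b[0] for b in bounds], dtype=float)
    hi = np.asarray([b[1] for b in bounds], dtype=float)
    if lo.ndim != 1 or np.any(lo >= hi):
        raise ValueError("each bound must satisfy lo < hi")
    dim = lo.size
    rng = np.random.default_rng(config.seed)

    x = rng.uniform(lo, hi, size=(config.swarm_size, dim))
    if x0 is not None:
        x[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
    v = rng.uniform(-(hi - lo), hi - lo, size=(config.swarm_size, dim)) * 0.1
    f = np.array([objective(xi) for xi in x])
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    trace = np.empty(config.iterations)
    for it in range(config.iterations):
        r1 = rng.random((config.swarm_size, dim))
        r2 = rng.random((config.swarm_size, dim))
        v = (
            config.inertia * v
            + config.cognitive * r1 * (pbest_x - x)
            + config.social * r2 * (gbest_x[None, :] - x)
        )
        x = np.clip(x + v, lo, hi)
        f = np.array([objective(xi) for xi in x])
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        trace[it] = gbest_f
    return PSOResult(best_x=gbest_x, best_f=gbest_f, trace=trace)


def _param_bounds(fis: MamdaniFIS, sigma_lo_frac: float = 0.01) -> list[tuple[float, float]]:
    """Box for the 16 MF parameters: means inside each universe, sigmas in
    [1%, 100%] of the universe width (no degenerate spikes)."""
    bounds = []
    for var in fis.variables:
        width = var.hi - var.lo
        bounds.extend(
            [
                (var.lo, var.hi),
                (sigma_lo_frac * width, width),
                (var.lo, var.hi),
                (sigma_lo_frac * width, width),
            ]
        )
    return bounds


def rmse_objective(
    params: np.ndarray,
    fis: MamdaniFIS,
    doses: np.ndarray,
    targets: np.ndarray,
) -> float:
    """RMSE of FIS predictions at ``params`` against observed rates.

    Invalid parameter vectors (non-positive sigma, mean outside its universe)
    return a large penalty rather than raising.
    """
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise ValueError("training pairs must be nonempty")
    params = np.asarray(params, dtype=float)
    for i, var in enumerate(fis.variables):
        ml, sl, mh, sh = params[4 * i : 4 * i + 4]
        if sl <= 0 or sh <= 0:
            return PENALTY
        if not (var.lo <= ml <= var.hi and var.lo <= mh <= var.hi):
            return PENALTY
    trial = copy.deepcopy(fis)
    trial.set_params(params)
    try:
        pred = trial.predict(doses)
    except ValueError:
        # e.g. memberships underflow to 0 and no rule fires: infeasible point
        return PENALTY
    return float(np.sqrt(np.mean((pred - targets) ** 2)))


@dataclass
class FitReport:
    train_rmse: float
    trace: np.ndarray
    seed: int
    validation_rmse: float | None = None
    initial_rmse: float | None = None
    extra: dict = field(default_factory=dict)


def tune_fis(
    fis: MamdaniFIS,
    doses: np.ndarray,
    rates: np.ndarray,
    config: PSOConfig | None = None,
    holdout: tuple[np.ndarray, np.ndarray] | None = None,
    n_restarts: int = 1,
) -> tuple[MamdaniFIS, FitReport]:
    """PSO-tune all 16 MF parameters of ``fis`` against (dose, rate) pairs.

    The template's own parameters warm-start the first swarm; additional
    ``n_restarts - 1`` swarms start fresh from derived seeds and the best run
    wins (PSO in 16 dimensions is multimodal enough that restarts pay off).
    Rule consequents are left untouched.  ``holdout`` is an optional
    (doses, rates) validation set (the fit-one-run / validate-the-next
    protocol); its RMSE is reported but never optimized.
    """
    config = config or PSOConfig()
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    doses = np.atleast_2d(np.asarray(doses, dtype=float))
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise ValueError("training pairs must be nonempty")
    if doses.shape != (rates.size, 3):
        raise ValueError("doses must be (n, 3) matching the rates vector")

    bounds = _param_bounds(fis)
    objective = lambda p: rmse_objective(p, fis, doses, rates)
    result = None
    for restart in range(n_restarts):
        cfg_r = replace(config, seed=config.seed + restart)
        run = pso_minimize(
            objective, bounds, cfg_r,
            x0=fis.get_params() if restart == 0 else None,
        )
        if result is None or run.best_f < result.best_f:
            result = run

    fitted = copy.deepcopy(fis)
    fitted.set_params(result.best_x)
    report = FitReport(
        train_rmse=result.best_f,
        trace=result.trace,
        seed=config.seed,
        initial_rmse=rmse_objective(fis.get_params(), fis, doses, rates),
    )
    if holdout is not None:
        h_doses, h_rates = holdout
        pred = fitted.predict(np.atleast_2d(np.asarray(h_doses, dtype=float)))
        report.validation_rmse = float(
            np.sqrt(np.mean((pred - np.asarray(h_rates, dtype=float)) ** 2))
        )
    fitted.metadata = dict(fitted.metadata)
    fitted.metadata.update(
        {"pso_seed": config.seed, "train_rmse": report.train_rmse}
    )
    return fitted, report
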