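"""Global fitting of latent (or native) parameters by basin-hopping.

Coordinates are optimized on the unit hypercube [0, 1]^d and mapped to the
physical (or latent) scale through per-coordinate bounds.  For latent fits
the bounds come from the observed latent ranges of the training pool, padded
by 5% on each side, and the forward map is the trained decoder (with analytic
gradients via backprop); for native fits the forward map is the simulator
itself (finite-difference gradients).

Basin-hopping (scipy) alternates a uniform random coordinate displacement of
magnitude <= 0.2 — clipped back into the hypercube — with a bounded
quasi-Newton (L-BFGS-B) local minimization of the residual sum of squares,
accepting hops with Metropolis probability

    P = exp(-(f_new - f_old) / T)

capped at 1, so improving steps are always accepted.  The temperature T
controls how freely the search crosses barriers and is adjusted per model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import basinhopping

__all__ = [
    "FitProblem",
    "FitResult",
    "objective",
    "acceptance_probability",
    "latent_bounds",
    "basin_hop",
    "decoder_problem",
]

logger = logging.getLogger("fixfit.fitting")

#: objective value substituted when the forward map fails
FORWARD_FAILURE_PENALTY = 1e9


@dataclass
class FitProblem:
    """A bounded global-fitting problem on the unit hypercube.

    forward
        Maps a coordinate vector on the *physical* scale (denormalized via
        ``bounds``) to a model output vector.
    target
        Output vector to fit.
    bounds
        (d, 2) array of per-coordinate (low, high) used to denormalize.
    grad
        Optional callable ``grad(x_phys, target) -> (rss, d rss / d x_phys)``;
        when absent the local optimizer uses finite differences.
    """

    forward: callable
    target: np.ndarray
    bounds: np.ndarray
    T: float = 1.0
    step_size: float = 0.2
    x0: np.ndarray | None = None
    niter: int = 100
    seed: int = 0
    grad: callable | None = None
    convergence_window: int = 25

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2 or np.any(~np.isfinite(self.bounds)):
            raise ValueError("bounds must be a finite (d, 2) array")
        if np.any(self.bounds[:, 1] <= self.bounds[:, 0]):
            raise ValueError("every bound needs low < high")
        self.target = np.asarray(self.target, dtype=float)
        if self.T <= 0:
            raise ValueError("temperature T must be positive")
        d = self.bounds.shape[0]
        if self.x0 is None:
            self.x0 = np.full(d, 0.5)
        self.x0 = np.asarray(self.x0, dtype=float)
        if self.x0.shape != (d,) or np.any(self.x0 < 0) or np.any(self.x0 > 1):
            raise ValueError("x0 must lie inside the unit hypercube")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    def denormalize(self, z: np.ndarray) -> np.ndarray:
        return self.bounds[:, 0] + np.asarray(z, dtype=float) * (self.bounds[:, 1] - self.bounds[:, 0])

    def normalize(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.bounds[:, 0]) / (self.bounds[:, 1] - self.bounds[:, 0])


@dataclass
class FitResult:
    x_best: np.ndarray          # normalized coordinates in [0, 1]^d
    x_best_denorm: np.ndarray
    fun: float                  # residual sum of squares at the optimum
    trace: list = field(default_factory=list)   # (z, objective) per evaluation
    hops: list = field(default_factory=list)    # (z, objective, accepted) per hop
    converged: bool = False

    def trace_frame(self) -> pd.DataFrame:
        rows = []
        for z, f in self.trace:
            rows.append({**{f"z{i}": v for i, v in enumerate(z)}, "objective": f})
        return pd.DataFrame(rows)

    def hops_frame(self) -> pd.DataFrame:
        rows = []
        for z, f, acc in self.hops:
            rows.append({**{f"z{i}": v for i, v in enumerate(z)}, "objective": f, "accepted": acc})
        return pd.DataFrame(rows)


def objective(z: np.ndarray, problem: FitProblem) -> float:
    """Residual sum of squares between forward(denorm(z)) and the target.

    Forward-map failures return a large penalty so the search can continue.
    """
    x = problem.denormalize(np.clip(z, 0.0, 1.0))
    try:
        pred = np.asarray(problem.forward(x), dtype=float)
    except (ValueError, RuntimeError, FloatingPointError) as exc:
        logger.debug("forward map failed at %s: %s", x, exc)
        return FORWARD_FAILURE_PENALTY
    resid = pred - problem.target
    rss = float(resid @ resid)
    return rss if np.isfinite(rss) else FORWARD_FAILURE_PENALTY


def acceptance_probability(f_new: float, f_old: float, T: float) -> float:
    """Metropolis hop-acceptance probability, capped at 1."""
    if T <= 0:
        raise ValueError("temperature T must be positive")
    return float(min(1.0, np.exp(min(0.0, -(f_new - f_old) / T))))


def latent_bounds(latent_matrix: np.ndarray, pad: float = 0.05) -> np.ndarray:
    """Per-coordinate (min, max) over a latent pool, padded by 5% of the range.

    The padded bounds contain every training latent and define the hypercube
    the latent fit searches.
    """
    latent_matrix = np.atleast_2d(np.asarray(latent_matrix, dtype=float))
    lo = latent_matrix.min(axis=0)
    hi = latent_matrix.max(axis=0)
    rng = hi - lo
    if np.any(rng <= 0):
        bad = int(np.argmin(rng))
        raise ValueError(f"latent coordinate {bad} has zero range; cannot build bounds")
    return np.column_stack([lo - pad * rng, hi + pad * rng])


class _ClippedUniformStep:
    """Uniform random displacement of magnitude <= stepsize, clipped to [0, 1]."""

    def __init__(self, stepsize: float, rng: np.random.Generator):
        self.stepsize = stepsize
        self.rng = rng

    def __call__(self, x: np.ndarray) -> np.ndarray:
        step = self.rng.uniform(-self.stepsize, self.stepsize, size=len(x))
        return np.clip(x + step, 0.0, 1.0)


def basin_hop(problem: FitProblem) -> FitResult:
    """Run seeded basin-hopping on a FitProblem and collect the full trace.

    Terminates early once the running best objective has been stable for
    ``problem.convergence_window`` consecutive hops.
    """
    trace: list = []
    hops: list = []

    def func(z):
        f = objective(z, problem)
        trace.append((z.copy(), f))
        return f

    minimizer_kwargs: dict = {
        "method": "L-BFGS-B",
        "bounds": [(0.0, 1.0)] * problem.dim,
    }
    if problem.grad is not None:
        def func_and_grad(z):
            zc = np.clip(z, 0.0, 1.0)
            x = problem.denormalize(zc)
            rss, g_phys = problem.grad(x, problem.target)
            trace.append((zc.copy(), float(rss)))
            return float(rss), g_phys * (problem.bounds[:, 1] - problem.bounds[:, 0])
        minimizer_kwargs["jac"] = True
        local_func = func_and_grad
    else:
        local_func = func

    rng = np.random.default_rng(problem.seed)
    state = {"best": np.inf, "streak": 0}

    def callback(x, f, accept):
        hops.append((x.copy(), float(f), bool(accept)))
        if f < state["best"] - 1e-15:
            state["best"] = f
            state["streak"] = 0
        else:
            state["streak"] += 1
        return state["streak"] >= problem.convergence_window

    res = basinhopping(
        local_func,
        problem.x0,
        niter=problem.niter,
        T=problem.T,
        take_step=_ClippedUniformStep(problem.step_size, rng),
        minimizer_kwargs=minimizer_kwargs,
        callback=callback,
        seed=rng,
    )
    if not trace:
        raise RuntimeError("basin-hopping performed no successful evaluation")
    z_best = np.clip(np.asarray(res.x, dtype=float), 0.0, 1.0)
    f_best = float(res.fun)
    converged = state["streak"] >= problem.convergence_window
    logger.info("basin-hopping: best RSS %.3e after %d hops (%d evaluations)%s",
                f_best, len(hops), len(trace), " [converged]" if converged else "")
    return FitResult(
        x_best=z_best,
        x_best_denorm=problem.denormalize(z_best),
        fun=f_best,
        trace=trace,
        hops=hops,
        converged=converged,
    )


def decoder_problem(model, target: np.ndarray, bounds: np.ndarray, **kwargs) -> FitProblem:
    """Latent-space FitProblem whose forward map is a trained decoder.

    Gradients are analytic (backprop through the decoder layers).
    """
    def forward(z_latent):
        return model.decode(z_latent)[0]

    def grad(z_latent, tgt):
        return model.decode_with_grad(z_latent, tgt)

    return FitProblem(forward=forward, target=target, bounds=bounds, grad=grad, **kwargs)
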