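"""Bayesian hyperparameter optimization with a Gaussian-process surrogate.

The tuning objective (cross-validated log-loss of the boosted classifier) is
treated as an expensive black box.  A zero-mean GP prior with the squared
exponential (RBF) kernel

    k(x, x') = exp(-||x - x'||^2 / (2 theta^2))

plus i.i.d. Gaussian observation noise models the objective over the search
space, normalized to the unit cube.  The posterior mean/variance at a
candidate x are the standard GP regression formulas

    mu(x)    = k' (K + s2 I)^{-1} y
    var(x)   = k(x, x) - k' (K + s2 I)^{-1} k

and candidates are scored by Expected Improvement under the minimization
convention.  Grid search and random search over the same space are provided
as baselines.  All routines are deterministic given their seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm, qmc

__all__ = [
    "Dimension",
    "SearchSpace",
    "GPSurrogate",
    "Posterior",
    "SpaceExhaustedError",
    "sef_kernel",
    "gp_posterior",
    "expected_improvement",
    "fit_length_scale",
    "propose_next",
    "bayes_optimize",
    "grid_search",
    "random_search",
    "default_space",
]

_JITTER = 1e-10


class SpaceExhaustedError(RuntimeError):
    """Every point of a finite (all-integer) space has been evaluated."""


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    kind: str = "continuous"  # or "integer"

    def __post_init__(self):
        if not self.low < self.high:
            raise ValueError(f"{self.name}: low must be < high")
        if self.kind not in ("continuous", "integer"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "integer" and (
            self.low != int(self.low) or self.high != int(self.high)
        ):
            raise ValueError(f"{self.name}: integer dims need integer bounds")


@dataclass(frozen=True)
class SearchSpace:
    """An ordered box of named dimensions, mapped to/from the unit cube."""

    dims: tuple[Dimension, ...]

    def __post_init__(self):
        object.__setattr__(self, "dims", tuple(self.dims))

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def to_unit(self, params: dict[str, float]) -> np.ndarray:
        return np.array(
            [(params[d.name] - d.low) / (d.high - d.low) for d in self.dims]
        )

    def from_unit(self, u: np.ndarray) -> dict[str, float]:
        out = {}
        for d, v in zip(self.dims, np.clip(np.asarray(u, float), 0.0, 1.0)):
            x = d.low + v * (d.high - d.low)
            out[d.name] = int(round(x)) if d.kind == "integer" else float(x)
        return out

    def n_integer_points(self) -> float:
        """Size of the space if every dimension is integer, else inf."""
        total = 1.0
        for d in self.dims:
            if d.kind != "integer":
                return math.inf
            total *= d.high - d.low + 1
        return total


def default_space() -> SearchSpace:
    """The six tuned hyperparameters of the boosted classifier."""
    return SearchSpace(
        (
            Dimension("N_estimators", 10, 300, "integer"),
            Dimension("Max_depth", 2, 12, "integer"),
            Dimension("Num_leaves", 8, 256, "integer"),
            Dimension("Subsample", 0.5, 1.0),
            Dimension("Colsample_bytree", 0.5, 1.0),
            Dimension("Min_child_samples", 2, 30, "integer"),
        )
    )


@dataclass
class GPSurrogate:
    """GP observations (in the unit cube), length scale and noise variance."""

    X: np.ndarray  # (t, d), all entries in [0, 1]
    y: np.ndarray  # (t,)
    theta: float = 0.5
    noise_var: float = 1e-6

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, float))
        self.y = np.asarray(self.y, float).ravel()
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.noise_var < 0:
            raise ValueError("noise_var must be non-negative")


@dataclass(frozen=True)
class Posterior:
    """GP predictive mean and variance at one query point."""

    mu: float
    var: float


def sef_kernel(x: np.ndarray, x2: np.ndarray, theta: float) -> float:
    """Squared exponential covariance exp(-||x-x2||^2 / (2 theta^2))."""
    if theta <= 0:
        raise ValueError(f"theta must be positive, got {theta}")
    x = np.asarray(x, float)
    x2 = np.asarray(x2, float)
    if x.shape != x2.shape:
        raise ValueError("points must have equal dimension")
    d2 = float(np.sum((x - x2) ** 2))
    return math.exp(-d2 / (2.0 * theta * theta))


def _gram(X: np.ndarray, Z: np.ndarray, theta: float) -> np.ndarray:
    d2 = np.sum((X[:, None, :] - Z[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * theta * theta))


def _posterior_batch(
    surrogate: GPSurrogate, Xq: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    X, y = surrogate.X, surrogate.y
    K = _gram(X, X, surrogate.theta)
    K[np.diag_indices_from(K)] += surrogate.noise_var + _JITTER
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"Gram matrix not positive definite (theta={surrogate.theta})"
        ) from exc
    kq = _gram(X, Xq, surrogate.theta)  # (t, m)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
    mu = kq.T @ alpha
    v = np.linalg.solve(L, kq)
    var = 1.0 - np.sum(v * v, axis=0)  # k(x, x) = 1 for the SEF kernel
    return mu, np.clip(var, 0.0, None)


def gp_posterior(surrogate: GPSurrogate, x: np.ndarray) -> Posterior:
    """Predictive distribution of the objective at *x* (GP regression)."""
    if len(surrogate.y) < 1:
        raise ValueError("surrogate needs at least one observation")
    Xq = np.atleast_2d(np.asarray(x, float))
    mu, var = _posterior_batch(surrogate, Xq)
    return Posterior(mu=float(mu[0]), var=float(var[0]))


def expected_improvement(post: Posterior, y_best: float, xi: float = 0.01) -> float:
    """Closed-form EI for minimization; 0 when the posterior is certain."""
    sigma = math.sqrt(max(post.var, 0.0))
    if sigma == 0.0:
        return 0.0
    improve = y_best - post.mu - xi
    z = improve / sigma
    return float(improve * norm.cdf(z) + sigma * norm.pdf(z))


def _ei_batch(mu: np.ndarray, var: np.ndarray, y_best: float, xi: float) -> np.ndarray:
    sigma = np.sqrt(np.clip(var, 0.0, None))
    improve = y_best - mu - xi
    out = np.zeros_like(mu)
    pos = sigma > 0
    z = improve[pos] / sigma[pos]
    out[pos] = improve[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return out


def fit_length_scale(
    X: np.ndarray,
    y: np.ndarray,
    noise_var: float = 1e-6,
    grid: np.ndarray | None = None,
) -> float:
    """Pick theta on a log grid by maximizing the GP log marginal likelihood."""
    if grid is None:
        grid = np.logspace(-2, 1, 25)
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = len(y)
    best_theta, best_ll = float(grid[0]), -np.inf
    for theta in grid:
        K = _gram(X, X, theta)
        K[np.diag_indices_from(K)] += noise_var + _JITTER
        try:
            L = np.linalg.cholesky(K)
        except np.linalg.LinAlgError:
            continue
        alpha = np.linalg.solve(L.T, np.linalg.solve(L, y))
        ll = (
            -0.5 * float(y @ alpha)
            - float(np.sum(np.log(np.diag(L))))
            - 0.5 * n * math.log(2.0 * math.pi)
        )
        if ll > best_ll:
            best_theta, best_ll = float(theta), ll
    return best_theta


def _dedupe_key(space: SearchSpace, params: dict[str, float]) -> tuple:
    return tuple(
        params[d.name] if d.kind == "integer" else round(params[d.name], 12)
        for d in space.dims
    )


def propose_next(
    surrogate: GPSurrogate,
    space: SearchSpace,
    rng: np.random.Generator,
    xi: float = 0.01,
    evaluated: set | None = None,
) -> dict[str, float]:
    """EI-maximizing next point over quasi-random + local candidates.

    Scores 2048 Sobol points in the unit cube plus 32 Gaussian perturbations
    of the incumbent, and returns the de-normalized argmax (integer dims
    rounded).  A candidate coinciding with an already-evaluated point is
    skipped in favour of the next-best; an all-integer space with no novel
    point left raises :class:`SpaceExhaustedError`.
    """
    if len(surrogate.y) < 1:
        raise ValueError("surrogate needs at least one observation")
    d = space.n_dims
    sobol = qmc.Sobol(d, scramble=True, seed=int(rng.integers(2**31)))
    cands = sobol.random_base2(11)  # 2048 points
    x_best = surrogate.X[int(np.argmin(surrogate.y))]
    local = np.clip(x_best + rng.normal(0.0, 0.05, size=(32, d)), 0.0, 1.0)
    cands = np.vstack([cands, local])
    mu, var = _posterior_batch(surrogate, cands)
    ei = _ei_batch(mu, var, float(np.min(surrogate.y)), xi)
    order = np.argsort(-ei)
    seen = evaluated if evaluated is not None else set()
    for idx in order:
        params = space.from_unit(cands[idx])
        if _dedupe_key(space, params) not in seen:
            return params
    if len(seen) >= space.n_integer_points():
        raise SpaceExhaustedError("all points of the integer space were evaluated")
    # all candidates collided but the space is not exhausted: jitter uniformly
    for _ in range(10000):
        params = space.from_unit(rng.uniform(size=d))
        if _dedupe_key(space, params) not in seen:
            return params
    raise SpaceExhaustedError("could not find a novel candidate point")


def _safe_eval(objective: Callable[[dict], float], params: dict[str, float]) -> float:
    try:
        val = float(objective(params))
    except Exception:
        return math.inf
    return val if math.isfinite(val) else math.inf


def _finish(history: list[tuple[dict, float]]):
    losses = [h[1] for h in history]
    i = int(np.argmin(losses))
    return history[i][0], history[i][1], history


def bayes_optimize(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_init: int = 10,
    n_iter: int = 40,
    seed: int | None = None,
    xi: float = 0.01,
    noise_var: float = 1e-6,
):
    """GP/EI minimization of *objective* over *space*.

    Evaluates the objective exactly ``n_init + n_iter`` times: ``n_init``
    Latin-hypercube points, then sequential EI proposals with the length
    scale refit each iteration by marginal-likelihood maximization over a
    log grid.  Objective failures count as +inf loss and the loop continues.
    Returns ``(best_params, best_loss, history)`` with the full (x, y) trace.
    """
    if n_init < 2:
        raise ValueError("n_init must be >= 2")
    rng = np.random.default_rng(seed)
    lhs = qmc.LatinHypercube(space.n_dims, seed=int(rng.integers(2**31)))
    history: list[tuple[dict, float]] = []
    X_unit: list[np.ndarray] = []
    evaluated: set = set()

    def record(u: np.ndarray, params: dict):
        loss = _safe_eval(objective, params)
        history.append((params, loss))
        X_unit.append(np.asarray(u, float))
        evaluated.add(_dedupe_key(space, params))

    for u in lhs.random(n_init):
        record(u, space.from_unit(u))

    for _ in range(n_iter):
        y = np.array([h[1] for h in history])
        finite = np.isfinite(y)
        if finite.any():
            mu_y = float(np.mean(y[finite]))
            sd_y = float(np.std(y[finite])) or 1.0
        else:
            mu_y, sd_y = 0.0, 1.0
        y_std = np.where(finite, (y - mu_y) / sd_y, 0.0)
        y_std[~finite] = (y_std[finite].max() if finite.any() else 0.0) + 10.0
        X = np.vstack(X_unit)
        theta = fit_length_scale(X, y_std, noise_var=noise_var)
        surrogate = GPSurrogate(X=X, y=y_std, theta=theta, noise_var=noise_var)
        try:
            params = propose_next(surrogate, space, rng, xi=xi, evaluated=evaluated)
        except SpaceExhaustedError:
            break
        record(space.to_unit(params), params)

    return _finish(history)


def grid_search(
    objective: Callable[[dict], float],
    space: SearchSpace,
    points_per_dim: int,
):
    """Exhaustive Cartesian-grid minimization (ties go to the first point)."""
    if points_per_dim < 1:
        raise ValueError("points_per_dim must be >= 1")
    axes = []
    for d in space.dims:
        vals = np.linspace(d.low, d.high, points_per_dim)
        if d.kind == "integer":
            vals = np.unique(np.round(vals).astype(int))
        axes.append(vals)
    total = math.prod(len(a) for a in axes)
    if total > 1_000_000:
        raise ValueError(f"grid of {total} points exceeds the 1e6 guard")
    history = []
    for combo in itertools.product(*axes):
        params = {
            d.name: (int(v) if d.kind == "integer" else float(v))
            for d, v in zip(space.dims, combo)
        }
        history.append((params, _safe_eval(objective, params)))
    return _finish(history)


def random_search(
    objective: Callable[[dict], float],
    space: SearchSpace,
    n_eval: int,
    seed: int | None = None,
):
    """Uniform i.i.d. sampling over the space; same contract as bayes_optimize."""
    if n_eval < 1:
        raise ValueError("n_eval must be >= 1")
    rng = np.random.default_rng(seed)
    history = []
    for _ in range(n_eval):
        params = space.from_unit(rng.uniform(size=space.n_dims))
        history.append((params, _safe_eval(objective, params)))
    return _finish(history)
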