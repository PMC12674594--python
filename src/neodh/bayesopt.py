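"""Bayesian optimization of the electron-proton correlation admixture.

The admixture fractions {b_epc, c_epc} are tuned against a dataset
RMSD objective with Gaussian-process regression (Matern-5/2 kernel)
and the expected-improvement acquisition function.  The parameter
space is the unit box; the one-parameter mode optimizes b_epc on the
diagonal c_epc = 1 - b_epc.  Budgets follow the reference protocol:
40 Latin-hypercube presamples + 20 acquisition points in 2-D, 10 + 3
in 1-D.

Acquisition maximization is a dense-grid argmax (2001 points in 1-D,
201x201 in 2-D): exact enough on a 1-2 dimensional box and exactly
reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern


@dataclass
class OptConfig:
    mode: str = "1d"                    # "1d" | "2d"
    bounds: tuple = ((0.0, 1.0),)       # per dimension
    presample: int | None = None        # default 10 (1d) / 40 (2d)
    acquisition: int | None = None      # default 3 (1d) / 20 (2d)
    seed: int = 0
    jitter: float = 1e-8
    n_restarts: int = 5

    def __post_init__(self):
        if self.mode not in ("1d", "2d"):
            raise ValueError("mode must be '1d' or '2d'")
        ndim = 1 if self.mode == "1d" else 2
        if len(self.bounds) == 1 and ndim == 2:
            self.bounds = (self.bounds[0], self.bounds[0])
        if len(self.bounds) != ndim:
            raise ValueError("bounds/mode dimension mismatch")
        for lo, hi in self.bounds:
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lower < upper")
        if self.presample is None:
            self.presample = 10 if ndim == 1 else 40
        if self.acquisition is None:
            self.acquisition = 3 if ndim == 1 else 20
        if self.presample < 1 or self.acquisition < 0:
            raise ValueError("counts must be positive")

    @property
    def ndim(self):
        return 1 if self.mode == "1d" else 2


@dataclass
class OptResult:
    points: np.ndarray              # (n, ndim) evaluated points
    values: np.ndarray              # objective values (nan = failed)
    best_point: np.ndarray
    best_value: float
    gp_kernel: str                  # fitted kernel at termination
    seed: int
    failed: list = field(default_factory=list)


def latin_hypercube(n: int, dims: int, bounds, seed: int) -> np.ndarray:
    """Latin hypercube sample: per dimension exactly one point in each
    of the n equal-width strata; reproducible under the seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=dims, seed=seed)
    u = sampler.random(n)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + u * (hi - lo)


class GPPosterior:
    """Thin wrapper over a fitted GP exposing mean/std functions."""

    def __init__(self, gp: GaussianProcessRegressor):
        self.gp = gp

    def __call__(self, X):
        m, s = self.gp.predict(np.atleast_2d(X), return_std=True)
        return m, s

    @property
    def kernel_(self):
        return self.gp.kernel_


def gp_posterior(X, y, seed: int = 0, jitter: float = 1e-8,
                 n_restarts: int = 5) -> GPPosterior:
    """Fit a Matern-5/2 GP (amplitude and length-scale by marginal
    likelihood maximization; observation noise is a fixed small jitter
    since the objective is deterministic)."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if len(X) < 2:
        raise ValueError("need at least two observations")
    if not np.all(np.isfinite(y)):
        raise ValueError("objective values must be finite")
    kernel = ConstantKernel(1.0, (1e-4, 1e4)) \
        * Matern(length_scale=0.2, length_scale_bounds=(1e-3, 1e2), nu=2.5)
    gp = GaussianProcessRegressor(kernel=kernel, alpha=jitter,
                                  normalize_y=True,
                                  n_restarts_optimizer=n_restarts,
                                  random_state=seed)
    gp.fit(X, y)
    return GPPosterior(gp)


def expected_improvement(posterior, best_so_far: float, candidates):
    """EI for minimization: E[max(best - Y, 0)] under the posterior."""
    mu, sd = posterior(candidates)
    imp = best_so_far - mu
    out = np.where(imp > 0.0, imp, 0.0)
    mask = sd > 1e-12
    z = np.zeros_like(mu)
    z[mask] = imp[mask] / sd[mask]
    out = np.where(mask, imp * norm.cdf(z) + sd * norm.pdf(z), out)
    return np.maximum(out, 0.0)


def _candidate_grid(config: OptConfig) -> np.ndarray:
    if config.ndim == 1:
        lo, hi = config.bounds[0]
        return np.linspace(lo, hi, 2001)[:, None]
    g = [np.linspace(lo, hi, 201) for lo, hi in config.bounds]
    A, B = np.meshgrid(g[0], g[1], indexing="ij")
    return np.column_stack([A.ravel(), B.ravel()])


def optimize_admixture(objective, config: OptConfig) -> OptResult:
    """Minimize ``objective`` over the admixture box.

    ``objective`` receives ``(b_epc, c_epc)``; in 1-D mode the search
    point is b_epc and c_epc = 1 - b_epc is implied.  Failed
    evaluations (exceptions) are recorded and skipped.  The objective
    is cached on the point rounded to 1e-6, so re-acquiring a
    numerically identical point costs nothing.
    """
    cache: dict[tuple, float] = {}
    failed: list = []

    def call(x):
        x = np.atleast_1d(x)
        if config.mode == "1d":
            pair = (float(x[0]), 1.0 - float(x[0]))
        else:
            pair = (float(x[0]), float(x[1]))
        key = tuple(round(v, 6) for v in pair)
        if key in cache:
            return cache[key]
        try:
            val = float(objective(*pair))
        except Exception as exc:      # objective failure: record, skip
            failed.append((pair, repr(exc)))
            val = math.nan
        cache[key] = val
        return val

    pts = list(latin_hypercube(config.presample, config.ndim,
                               config.bounds, config.seed))
    vals = [call(p) for p in pts]
    grid = _candidate_grid(config)
    post = None
    for k in range(config.acquisition):
        ok = np.isfinite(vals)
        X = np.array(pts)[ok]
        y = np.array(vals)[ok]
        if len(X) < 2:
            # not enough successes to model: fall back to more LHS
            newp = latin_hypercube(1, config.ndim, config.bounds,
                                   config.seed + 1000 + k)[0]
        else:
            post = gp_posterior(X, y, seed=config.seed,
                                jitter=config.jitter,
                                n_restarts=config.n_restarts)
            ei = expected_improvement(post, float(y.min()), grid)
            newp = grid[int(np.argmax(ei))]
        pts.append(newp)
        vals.append(call(newp))
    vals = np.array(vals)
    pts = np.array(pts)
    ok = np.isfinite(vals)
    ibest = int(np.flatnonzero(ok)[np.argmin(vals[ok])])
    return OptResult(points=pts, values=vals,
                     best_point=pts[ibest].copy(),
                     best_value=float(vals[ibest]),
                     gp_kernel=str(post.kernel_) if post is not None else "",
                     seed=config.seed, failed=failed)
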