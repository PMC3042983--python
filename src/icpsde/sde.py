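"""Stochastic simulation of the CSF pressure SDE.

The pressure follows the Ito stochastic differential equation

    dp = (alpha·p − beta·p²) dt + noise_amp·p dW,

a stochastic logistic (Verhulst) process with multiplicative noise:
fluctuations in the CSF inflow rate enter the dynamics proportionally
to the current pressure.  This module provides

* Brownian-path sampling on arbitrary time grids,
* two discretisation schemes — plain Euler–Maruyama on ``p`` and an
  Ito-transformed Euler scheme on ``ln p`` (positivity-preserving), both
  driven by the same Brownian increments for a given seed,
* the closed-form pathwise solution

      p(t) = N(t) / D(t),
      N(t) = exp[(alpha − noise_amp²/2)·t + noise_amp·W(t)],
      D(t) = 1/p_init + beta·∫₀ᵗ exp[(alpha − noise_amp²/2)s + noise_amp·W(s)] ds,

  evaluated entirely in log space (the integral uses an exponential
  quadrature rule that treats the exponent as piecewise linear between
  grid points, so the noise-free case reduces to the deterministic
  logistic solution to machine precision on any grid), and
* ensemble simulation with deterministically derived per-path seeds.

The Ito convention is fixed throughout; there is no Stratonovich mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, GridMismatchError, PositivityBreachError
from .model import CSFModelParams, deterministic_solution

__all__ = [
    "TimeGrid",
    "BrownianPath",
    "ICPTrajectory",
    "EnsembleSummary",
    "sample_brownian_path",
    "simulate_path",
    "exact_path_solution",
    "simulate_ensemble",
    "euler_maruyama_on_path",
    "log_euler_on_path",
]

SCHEMES = ("euler-maruyama", "log-euler", "exact-path", "deterministic")


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing time grid (minutes) starting at 0."""

    t: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise DomainError("time grid must be 1-D with at least two points")
        if t[0] != 0.0:
            raise DomainError("time grid must start at t = 0")
        if np.any(np.diff(t) <= 0):
            raise DomainError("time grid must be strictly increasing")
        t = t.copy()
        t.setflags(write=False)
        object.__setattr__(self, "t", t)

    @classmethod
    def uniform(cls, dt: float, T: float) -> "TimeGrid":
        """Uniform grid with nominal step ``dt`` covering [0, T]."""
        if dt <= 0 or T <= 0:
            raise DomainError("dt and T must be positive")
        n = int(round(T / dt))
        if n < 1:
            raise DomainError("T must cover at least one step")
        return cls(np.linspace(0.0, n * dt, n + 1))

    @property
    def steps(self) -> np.ndarray:
        """Step lengths, minutes."""
        return np.diff(self.t)

    @property
    def dt(self) -> float:
        """Nominal (median) step, minutes."""
        return float(np.median(self.steps))

    @property
    def n_steps(self) -> int:
        return self.t.size - 1


@dataclass(frozen=True)
class BrownianPath:
    """A sampled standard Brownian motion W(t) on a time grid.

    ``W[0] = 0`` and increments over a step of length ``dt`` are
    independent N(0, dt) (units of √min; W itself is dimensionless in
    the model because noise_amp carries min⁻¹).
    """

    grid: TimeGrid
    W: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != self.grid.t.shape:
            raise GridMismatchError("W must have one value per grid time")
        if W[0] != 0.0:
            raise DomainError("Brownian path must start at W(0) = 0")
        W = W.copy()
        W.setflags(write=False)
        object.__setattr__(self, "W", W)

    @property
    def increments(self) -> np.ndarray:
        return np.diff(self.W)


@dataclass(frozen=True)
class ICPTrajectory:
    """An ICP sample path p(t) in mmHg on a time grid, with provenance."""

    grid: TimeGrid
    p: np.ndarray
    scheme: str
    seed: int | None = None
    params: CSFModelParams | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != self.grid.t.shape:
            raise GridMismatchError("p must have one value per grid time")
        if self.scheme in ("log-euler", "exact-path", "deterministic") and np.any(
            p <= 0
        ):
            raise DomainError(f"scheme {self.scheme!r} must yield positive pressures")
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class EnsembleSummary:
    """Cross-sectional summary of an ensemble of ICP paths."""

    grid: TimeGrid
    mean: np.ndarray  # mmHg
    sd: np.ndarray  # mmHg
    quantiles: dict[float, np.ndarray] = field(default_factory=dict)
    n_paths: int = 0


# ---------------------------------------------------------------------------
# Brownian sampling and seed derivation


def _path_rng(master_seed: int, path_index: int) -> np.random.Generator:
    """Counter-based per-path RNG: path ``i`` always gets the same stream
    for a given master seed, independent of the ensemble size."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(path_index),))
    )


def sample_brownian_path(grid: TimeGrid, seed: int) -> BrownianPath:
    """Sample a Brownian path on ``grid`` (reproducible for a fixed seed)."""
    rng = np.random.default_rng(int(seed))
    dW = rng.standard_normal(grid.n_steps) * np.sqrt(grid.steps)
    W = np.concatenate([[0.0], np.cumsum(dW)])
    return BrownianPath(grid=grid, W=W, seed=int(seed))


# ---------------------------------------------------------------------------
# Discretisation schemes (time-major, vectorised across paths)


def _euler_paths(
    params: CSFModelParams, steps: np.ndarray, dW: np.ndarray, p_init: float
) -> np.ndarray:
    """Euler–Maruyama on p for dW of shape (m, n); returns (m, n+1)."""
    a, b, s = params.alpha, params.beta, params.noise_amp
    m, n = dW.shape
    p = np.empty((m, n + 1))
    p[:, 0] = p_init
    cur = np.full(m, float(p_init))
    for k in range(n):
        cur = cur + (a * cur - b * cur * cur) * steps[k] + s * cur * dW[:, k]
        if np.any(cur <= 0):
            raise PositivityBreachError(k)
        p[:, k + 1] = cur
    return p


def _log_euler_paths(
    params: CSFModelParams, steps: np.ndarray, dW: np.ndarray, p_init: float
) -> np.ndarray:
    """Ito-transformed Euler on y = ln p; strictly positive by construction."""
    a, b, s = params.alpha, params.beta, params.noise_amp
    m, n = dW.shape
    y = np.empty((m, n + 1))
    y[:, 0] = np.log(p_init)
    cur = np.full(m, np.log(p_init))
    drift_const = a - 0.5 * s * s
    for k in range(n):
        cur = cur + (drift_const - b * np.exp(cur)) * steps[k] + s * dW[:, k]
        y[:, k + 1] = cur
    return np.exp(y)


def euler_maruyama_on_path(
    params: CSFModelParams, path: BrownianPath, p_init: float
) -> ICPTrajectory:
    """Euler–Maruyama discretisation of the SDE along a given Brownian path.

    Raises :class:`PositivityBreachError` (with the step index) if the
    iterate crosses zero instead of continuing silently.
    """
    if p_init <= 0:
        raise DomainError(f"p_init must be > 0 mmHg, got {p_init}")
    p = _euler_paths(params, path.grid.steps, path.increments[None, :], p_init)[0]
    return ICPTrajectory(path.grid, p, "euler-maruyama", path.seed, params)


def log_euler_on_path(
    params: CSFModelParams, path: BrownianPath, p_init: float
) -> ICPTrajectory:
    """Positivity-preserving Euler scheme on ln p along a Brownian path."""
    if p_init <= 0:
        raise DomainError(f"p_init must be > 0 mmHg, got {p_init}")
    p = _log_euler_paths(params, path.grid.steps, path.increments[None, :], p_init)[0]
    return ICPTrajectory(path.grid, p, "log-euler", path.seed, params)


def simulate_path(
    params: CSFModelParams,
    grid: TimeGrid,
    p_init: float,
    seed: int,
    scheme: str = "log-euler",
) -> ICPTrajectory:
    """Simulate one ICP path on ``grid`` from ``p_init`` (mmHg).

    The Brownian increments depend only on ``(grid, seed)``, so the two
    schemes driven by the same seed see the same noise realisation.
    """
    if scheme not in ("euler-maruyama", "log-euler"):
        raise DomainError(f"unknown scheme {scheme!r}")
    path = sample_brownian_path(grid, seed)
    if scheme == "euler-maruyama":
        return euler_maruyama_on_path(params, path, p_init)
    return log_euler_on_path(params, path, p_init)


# ---------------------------------------------------------------------------
# Closed-form pathwise solution


def _log_exp_integral_cum(g: np.ndarray, steps: np.ndarray) -> np.ndarray:
    """Cumulative log of ∫ exp(g(s)) ds along the grid.

    Treats g as piecewise linear between grid points, for which the
    integral over one step is dt·(e^{g1} − e^{g0})/(g1 − g0); evaluated
    in log space so exponents of magnitude ~10³ are safe.  Returns, for
    each k ≥ 1, log ∫₀^{t_k}; shape g.shape[:-1] + (n,).
    """
    g0 = g[..., :-1]
    dg = np.diff(g, axis=-1)
    # log((e^dg - 1)/dg), stable for dg of any sign/magnitude
    adg = np.abs(dg)
    with np.errstate(divide="ignore", invalid="ignore"):
        core = np.where(
            adg < 1e-6,
            0.5 * dg + dg * dg / 24.0,  # series of log((e^x-1)/x)
            np.where(
                dg > 0,
                dg + np.log1p(-np.exp(-np.where(dg > 0, dg, 1.0))) - np.log(adg),
                np.log1p(-np.exp(-adg)) - np.log(adg),  # dg<0: (1-e^dg)/|dg|
            ),
        )
    log_terms = np.log(steps) + g0 + core
    return np.logaddexp.accumulate(log_terms, axis=-1)


def exact_path_solution(
    params: CSFModelParams, path: BrownianPath, p_init: float
) -> ICPTrajectory:
    """Evaluate the closed-form solution of the SDE along a Brownian path.

    All arithmetic is carried out in log space: the numerator exponent
    ``g(t) = (alpha − noise_amp²/2)t + noise_amp·W(t)`` can reach
    magnitudes of order 10³ at physiological parameters without
    overflow.  With ``W ≡ 0`` and ``sigma = 0`` the result coincides
    with the deterministic logistic solution to machine precision.
    """
    if p_init <= 0:
        raise DomainError(f"p_init must be > 0 mmHg, got {p_init}")
    t = path.grid.t
    g = (params.alpha - 0.5 * params.noise_amp**2) * t + params.noise_amp * path.W
    log_int = _log_exp_integral_cum(g, path.grid.steps)
    log_beta = np.log(params.beta)
    logD = np.empty_like(t)
    logD[0] = -np.log(p_init)
    logD[1:] = np.logaddexp(-np.log(p_init), log_beta + log_int)
    p = np.exp(g - logD)
    return ICPTrajectory(path.grid, p, "exact-path", path.seed, params)


# ---------------------------------------------------------------------------
# Ensembles


def simulate_ensemble(
    params: CSFModelParams,
    grid: TimeGrid,
    p_init: float,
    n_paths: int,
    seed: int,
    scheme: str = "log-euler",
    quantile_levels: tuple[float, ...] = (0.05, 0.25, 0.5, 0.75, 0.95),
    path_chunk: int = 256,
) -> EnsembleSummary:
    """Cross-sectional summary of ``n_paths`` independent ICP paths.

    Per-path seeds derive from the master seed by a counter rule
    (seed sequence spawned with the path index), so path ``i`` is the
    same regardless of the ensemble size and paths can be regenerated
    individually.  Paths are processed in chunks of ``path_chunk`` to
    bound memory on long grids.
    """
    if n_paths < 1:
        raise DomainError("n_paths must be >= 1")
    if p_init <= 0:
        raise DomainError(f"p_init must be > 0 mmHg, got {p_init}")
    if scheme not in ("euler-maruyama", "log-euler"):
        raise DomainError(f"unknown scheme {scheme!r}")
    steps = grid.steps
    sqrt_steps = np.sqrt(steps)
    integrate = _euler_paths if scheme == "euler-maruyama" else _log_euler_paths

    all_p = np.empty((n_paths, grid.t.size))
    for lo in range(0, n_paths, path_chunk):
        hi = min(lo + path_chunk, n_paths)
        dW = np.empty((hi - lo, grid.n_steps))
        for i in range(lo, hi):
            dW[i - lo] = _path_rng(seed, i).standard_normal(grid.n_steps) * sqrt_steps
        all_p[lo:hi] = integrate(params, steps, dW, p_init)

    mean = all_p.mean(axis=0)
    sd = all_p.std(axis=0, ddof=1) if n_paths > 1 else np.zeros_like(mean)
    quantiles = {
        float(q): np.quantile(all_p, q, axis=0) for q in sorted(quantile_levels)
    }
    return EnsembleSummary(grid=grid, mean=mean, sd=sd, quantiles=quantiles, n_paths=n_paths)


def deterministic_trajectory(
    params: CSFModelParams, grid: TimeGrid, p_init: float
) -> ICPTrajectory:
    """The noise-free logistic solution sampled on ``grid``."""
    p = deterministic_solution(grid.t, p_init, params)
    return ICPTrajectory(grid, np.asarray(p), "deterministic", None, params)
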