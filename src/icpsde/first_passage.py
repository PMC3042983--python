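"""First-passage (clinical-risk) probabilities for the ICP process.

Given a patient whose ICP is currently ``x`` mmHg, the probability of
reaching a critical level ``b`` (default 40 mmHg, the lower end of the
40–50 mmHg range patients have been reported to tolerate) before
falling to a lower level ``a`` is the classical two-barrier hitting
probability of a one-dimensional diffusion,

    u(x) = (S(x) − S(a)) / (S(b) − S(a)),

where ``S`` is the scale function, ``S(x) = ∫ˣ s(η) dη``, and the scale
density is

    s(p) = exp( −∫ᵖ 2·drift(ξ)/diffusion(ξ)² dξ )
         = exp( −(2/(σ²E)) [ (I + p_b/R)·ln p − p/R ] )

up to an arbitrary positive factor that cancels in ``u``.  The inner
integral is elementary; the outer one is not, and is computed by
Gauss–Legendre quadrature *in log space* (log-sum-exp), because at the
reference parameters the linear-space integrand spans hundreds of
orders of magnitude.

The level ``p = 0`` is an entrance boundary whenever the stationary
distribution exists (the scale integral diverges there), so the
two-barrier probability with ``a → 0`` is identically 1 — the
degenerate limit of the textbook formulation with ``u(0) = 0``.  A
positive lower level ``a`` (default 30 mmHg for the 35 → 40 mmHg risk
scenarios) keeps the question well posed;
:func:`paper_bvp_probability` retains the two-point boundary-value
formulation with a small cutoff ``epsilon`` as an explicit replication
mode.  A log-Euler Monte-Carlo estimator cross-validates the analytic
route.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.linalg import solve_banded
from scipy.special import logsumexp

from .exceptions import DomainError, HorizonError
from .model import CSFModelParams, deterministic_equilibrium

__all__ = [
    "HittingProblem",
    "RiskCurve",
    "RiskSurface",
    "MCEstimate",
    "scale_log_density",
    "log_scale_increment",
    "hitting_probability",
    "log_hitting_probability",
    "deterministic_hitting",
    "paper_bvp_probability",
    "mc_hitting_probability",
    "risk_curve_over_sigma",
    "risk_curve_over_R",
    "risk_surface",
]

logger = logging.getLogger(__name__)

#: Default grids for the risk curves and surface: noise intensity
#: 0.4–1.3 mL/min and outflow resistance 4–12 mmHg·mL⁻¹·min.
DEFAULT_SIGMA_GRID = np.round(np.arange(0.4, 1.3 + 0.025, 0.05), 10)
DEFAULT_R_GRID = np.round(np.arange(4.0, 12.0 + 0.25, 0.5), 10)


@dataclass(frozen=True)
class HittingProblem:
    """A two-barrier first-passage query: reach ``b`` before ``a`` from ``x``.

    Invariants: ``0 < a <= x <= b`` and ``a < b``; all in mmHg.
    """

    x: float
    b: float
    a: float
    params: CSFModelParams

    def __post_init__(self) -> None:
        if not (0 < self.a <= self.x <= self.b):
            raise DomainError(
                f"require 0 < a <= x <= b, got a={self.a}, x={self.x}, b={self.b}"
            )
        if self.a >= self.b:
            raise DomainError("require a < b")


@dataclass(frozen=True)
class RiskCurve:
    """Hitting probabilities along one parameter axis, others fixed."""

    axis: str  # "sigma" or "R"
    grid: np.ndarray
    probabilities: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if self.axis not in ("sigma", "R"):
            raise DomainError(f"axis must be 'sigma' or 'R', got {self.axis!r}")
        if np.any(np.diff(g) <= 0):
            raise DomainError("grid must be strictly increasing")
        if g.shape != p.shape:
            raise DomainError("grid and probabilities must have equal shape")
        if np.any((p < 0) | (p > 1)):
            raise DomainError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "probabilities", p)


@dataclass(frozen=True)
class RiskSurface:
    """Hitting probabilities over an (R, sigma) grid; entry [i, j] is
    evaluated at ``R_grid[i]``, ``sigma_grid[j]``."""

    R_grid: np.ndarray
    sigma_grid: np.ndarray
    probabilities: np.ndarray
    fixed: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        P = np.asarray(self.probabilities, dtype=float)
        if P.shape != (len(self.R_grid), len(self.sigma_grid)):
            raise DomainError("probability matrix shape must be (len(R), len(sigma))")
        if np.any((P < 0) | (P > 1)):
            raise DomainError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class MCEstimate:
    """Monte-Carlo two-barrier probability with its binomial standard error.

    ``probability`` is the fraction of *uncensored* paths that reached
    ``b`` before ``a``; paths still between the barriers at the horizon
    are counted in ``censored_fraction``, never silently dropped.
    """

    probability: float
    se: float
    n_paths: int
    dt: float
    t_max: float
    censored_fraction: float


# ---------------------------------------------------------------------------
# Scale density and scale-function increments


def scale_log_density(p, params: CSFModelParams):
    """log s(p): the log scale density, up to an additive constant.

    ``log s(p) = −(2/(σ²E)) [ (I + p_b/R)·ln p − p/R ]``.  All consumers
    use differences, so the arbitrary constant (the anchor of the inner
    integral) is irrelevant.  Minimised at the deterministic equilibrium
    ``R·I + p_b``, where the drift vanishes.
    """
    if params.sigma == 0:
        raise DomainError("scale density undefined for sigma = 0")
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise DomainError("scale_log_density requires p > 0 mmHg")
    c = 2.0 / (params.sigma**2 * params.E)
    out = -c * ((params.I + params.p_b / params.R) * np.log(p) - p / params.R)
    return out if out.ndim else float(out)


def log_scale_increment(
    p_lo: float,
    p_hi: float,
    params: CSFModelParams,
    n_nodes: int | None = None,
) -> float:
    """log ∫ s(η) dη over [p_lo, p_hi], computed stably in log space.

    Composite Gauss–Legendre of order 16 per panel; when ``n_nodes`` is
    given, roughly that many nodes are used, otherwise the panel count
    doubles until the log-integral changes by less than 1e-8.  Finite
    for all valid inputs even when the linear-space integrand over- or
    underflows (exponents of magnitude ~10³ at the reference
    parameters).
    """
    if not (0 < p_lo < p_hi):
        raise DomainError(f"require 0 < p_lo < p_hi, got ({p_lo}, {p_hi})")
    order = 16
    nodes01, weights = leggauss(order)

    def composite(n_panels: int) -> float:
        edges = np.linspace(p_lo, p_hi, n_panels + 1)
        mid = 0.5 * (edges[1:] + edges[:-1])
        half = 0.5 * np.diff(edges)
        # nodes: (n_panels, order)
        xs = mid[:, None] + half[:, None] * nodes01[None, :]
        log_vals = scale_log_density(xs, params) + np.log(half)[:, None] + np.log(
            weights
        )[None, :]
        return float(logsumexp(log_vals))

    if n_nodes is not None:
        if n_nodes < 2:
            raise DomainError("n_nodes must be >= 2")
        return composite(max(1, int(np.ceil(n_nodes / order))))

    n_panels, prev = 1, composite(1)
    for _ in range(12):
        n_panels *= 2
        cur = composite(n_panels)
        if abs(cur - prev) < 1e-8:
            return cur
        prev = cur
    return prev


# ---------------------------------------------------------------------------
# Hitting probabilities


def log_hitting_probability(prob: HittingProblem) -> float:
    """log u(x); finite even when u underflows in linear space."""
    if prob.params.sigma == 0:
        raise DomainError(
            "hitting probability undefined at sigma = 0; use "
            "deterministic_hitting() for the noise-free limit"
        )
    if prob.x == prob.a:
        return -np.inf
    if prob.x == prob.b:
        return 0.0
    num = log_scale_increment(prob.a, prob.x, prob.params)
    den = log_scale_increment(prob.a, prob.b, prob.params)
    return min(num - den, 0.0)


def hitting_probability(prob: HittingProblem) -> float:
    """P[reach b before a | ICP = x] = (S(x) − S(a))/(S(b) − S(a)).

    Computed entirely via log-space scale-function increments; the
    result is exact 0 at ``x = a``, exact 1 at ``x = b`` and
    nondecreasing in ``x``.  Signals :class:`DomainError` at
    ``sigma = 0`` (see :func:`deterministic_hitting`).
    """
    return float(np.exp(log_hitting_probability(prob)))


def deterministic_hitting(x: float, a: float, b: float, params: CSFModelParams) -> float:
    """Noise-free limit of the two-barrier probability: 0 or 1.

    The deterministic flow from ``x`` moves monotonically toward the
    equilibrium ``R·I + p_b``; it reaches ``b`` (before ``a``) iff the
    equilibrium lies at or above ``b``.
    """
    if not (0 < a <= x <= b) or a >= b:
        raise DomainError("require 0 < a <= x <= b with a < b")
    if x == b:
        return 1.0
    if x == a:
        return 0.0
    return 1.0 if deterministic_equilibrium(params) >= b else 0.0


def paper_bvp_probability(
    x: float,
    b: float,
    params: CSFModelParams,
    epsilon: float,
    n_grid: int = 10_001,
) -> float:
    """Replication mode: the two-point boundary-value formulation.

    Solves the hitting ODE

        (σ²E²ξ²/2)·u'' + (E·I·ξ − E·ξ(ξ − p_b)/R)·u' = 0,
        u(epsilon) = 0,  u(b) = 1,

    by central finite differences on a uniform grid over
    ``[epsilon, b]`` and interpolates at ``x``.  The ODE is singular at
    0 — and when the stationary distribution exists, the exact
    ``epsilon → 0`` limit is ``u ≡ 1`` for every ``x > 0`` — so a
    strictly positive cutoff is required.  Equivalent to
    :func:`hitting_probability` with ``a = epsilon``.
    """
    if epsilon <= 0:
        raise DomainError(
            "epsilon must be > 0: the hitting ODE is singular at 0 and the "
            "exact epsilon->0 limit is u == 1 whenever the stationary "
            "distribution exists"
        )
    if not (epsilon < x < b):
        raise DomainError("require epsilon < x < b")
    if params.sigma == 0:
        raise DomainError("BVP undefined for sigma = 0")
    if n_grid < 3:
        raise DomainError("n_grid must be >= 3")
    xi = np.linspace(epsilon, b, n_grid)
    h = xi[1] - xi[0]
    interior = xi[1:-1]
    D = 0.5 * (params.noise_amp * interior) ** 2  # diffusion^2/2
    M = params.alpha * interior - params.beta * interior**2  # drift
    lower = D / h**2 - M / (2 * h)
    diag = -2.0 * D / h**2
    upper = D / h**2 + M / (2 * h)
    rhs = np.zeros(n_grid - 2)
    rhs[0] -= lower[0] * 0.0  # u(epsilon) = 0
    rhs[-1] -= upper[-1] * 1.0  # u(b) = 1
    ab = np.zeros((3, n_grid - 2))
    ab[0, 1:] = upper[:-1]
    ab[1, :] = diag
    ab[2, :-1] = lower[1:]
    u_in = solve_banded((1, 1), ab, rhs)
    u = np.concatenate([[0.0], u_in, [1.0]])
    # FD round-off can overshoot the boundary values by O(1e-10)
    return float(np.clip(np.interp(x, xi, u), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Monte-Carlo cross-validation


def mc_hitting_probability(
    prob: HittingProblem,
    n_paths: int = 20_000,
    dt: float = 5e-4,
    t_max: float = 60.0,
    seed: int = 0,
) -> MCEstimate:
    """Monte-Carlo two-barrier probability via log-Euler paths.

    Barrier crossings are detected by level comparison at grid times
    (no Brownian-bridge correction), which biases the estimate by
    O(√dt); comparisons against the analytic route should allow for
    this.  Paths that hit neither barrier within ``t_max`` are counted
    as censored; more than 1% censoring signals :class:`HorizonError`.
    """
    if n_paths < 100:
        raise DomainError("n_paths must be >= 100")
    if dt <= 0 or t_max <= 0:
        raise DomainError("dt and t_max must be positive")
    params = prob.params
    if params.sigma == 0:
        raise DomainError("Monte-Carlo estimator requires sigma > 0")
    a_lvl, b_lvl = prob.a, prob.b
    rng = np.random.default_rng(int(seed))
    alpha, beta, s = params.alpha, params.beta, params.noise_amp
    drift_const = alpha - 0.5 * s * s
    sqrt_dt = np.sqrt(dt)
    n_steps = int(np.ceil(t_max / dt))

    y = np.full(n_paths, np.log(prob.x))
    n_hit_b = 0
    n_hit_a = 0
    # immediate absorptions at the start level
    if prob.x >= b_lvl:
        return MCEstimate(1.0, 0.0, n_paths, dt, t_max, 0.0)
    if prob.x <= a_lvl:
        return MCEstimate(0.0, 0.0, n_paths, dt, t_max, 0.0)
    log_a, log_b = np.log(a_lvl), np.log(b_lvl)
    for _ in range(n_steps):
        if y.size == 0:
            break
        dW = rng.standard_normal(y.size) * sqrt_dt
        y = y + (drift_const - beta * np.exp(y)) * dt + s * dW
        hit_b = y >= log_b
        hit_a = (~hit_b) & (y <= log_a)
        n_hit_b += int(hit_b.sum())
        n_hit_a += int(hit_a.sum())
        y = y[~(hit_b | hit_a)]
    n_censored = y.size
    censored_fraction = n_censored / n_paths
    if censored_fraction > 0.01:
        raise HorizonError(
            f"{censored_fraction:.1%} of paths hit neither barrier within "
            f"t_max = {t_max} min; extend the horizon"
        )
    n_dec = n_hit_a + n_hit_b
    p_hat = n_hit_b / n_dec if n_dec else float("nan")
    se = float(np.sqrt(p_hat * (1 - p_hat) / n_dec)) if n_dec else float("nan")
    return MCEstimate(p_hat, se, n_paths, dt, t_max, censored_fraction)


# ---------------------------------------------------------------------------
# Risk curves and surfaces


def _check_curve_shape(axis: str, grid: np.ndarray, probs: np.ndarray) -> None:
    """Report (do not hide) violations of the expected monotone shape."""
    diffs = np.diff(probs)
    if np.any(diffs < -1e-12):
        logger.warning(
            "risk curve over %s is not nondecreasing at indices %s",
            axis,
            np.nonzero(diffs < -1e-12)[0].tolist(),
        )


def risk_curve_over_sigma(
    params: CSFModelParams,
    sigma_grid=DEFAULT_SIGMA_GRID,
    x: float = 35.0,
    a: float = 30.0,
    b: float = 40.0,
) -> RiskCurve:
    """Hitting probability as a function of noise intensity σ (mL/min)."""
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if np.any(sigma_grid <= 0):
        raise DomainError("sigma grid must be positive")
    probs = np.empty_like(sigma_grid)
    for i, s in enumerate(sigma_grid):
        try:
            probs[i] = hitting_probability(
                HittingProblem(x=x, b=b, a=a, params=params.replace(sigma=float(s)))
            )
        except Exception as exc:  # annotate with the grid index
            raise type(exc)(f"at sigma grid index {i} (sigma={s}): {exc}") from exc
    _check_curve_shape("sigma", sigma_grid, probs)
    fixed = params.to_dict() | {"x": x, "a": a, "b": b}
    del fixed["sigma"]
    return RiskCurve(axis="sigma", grid=sigma_grid, probabilities=probs, fixed=fixed)


def risk_curve_over_R(
    params: CSFModelParams,
    R_grid=DEFAULT_R_GRID,
    x: float = 35.0,
    a: float = 30.0,
    b: float = 40.0,
) -> RiskCurve:
    """Hitting probability as a function of outflow resistance R
    (mmHg·mL⁻¹·min), σ fixed at ``params.sigma``."""
    R_grid = np.asarray(R_grid, dtype=float)
    if np.any(R_grid <= 0):
        raise DomainError("R grid must be positive")
    probs = np.empty_like(R_grid)
    for i, r in enumerate(R_grid):
        try:
            probs[i] = hitting_probability(
                HittingProblem(x=x, b=b, a=a, params=params.replace(R=float(r)))
            )
        except Exception as exc:
            raise type(exc)(f"at R grid index {i} (R={r}): {exc}") from exc
    _check_curve_shape("R", R_grid, probs)
    fixed = params.to_dict() | {"x": x, "a": a, "b": b}
    del fixed["R"]
    return RiskCurve(axis="R", grid=R_grid, probabilities=probs, fixed=fixed)


def risk_surface(
    params: CSFModelParams,
    R_grid=DEFAULT_R_GRID,
    sigma_grid=DEFAULT_SIGMA_GRID,
    x: float = 35.0,
    a: float = 30.0,
    b: float = 40.0,
) -> RiskSurface:
    """Hitting probability over the (R, σ) plane.

    Row ``i`` of the matrix is the σ-curve at ``R_grid[i]``; column
    ``j`` is the R-curve at ``sigma_grid[j]``.  Probabilities increase
    toward the high-σ, high-R corner.
    """
    R_grid = np.asarray(R_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    P = np.empty((R_grid.size, sigma_grid.size))
    for i, r in enumerate(R_grid):
        for j, s in enumerate(sigma_grid):
            try:
                P[i, j] = hitting_probability(
                    HittingProblem(
                        x=x, b=b, a=a,
                        params=params.replace(R=float(r), sigma=float(s)),
                    )
                )
            except Exception as exc:
                raise type(exc)(f"at (R={r}, sigma={s}): {exc}") from exc
    fixed = params.to_dict() | {"x": x, "a": a, "b": b}
    del fixed["R"], fixed["sigma"]
    return RiskSurface(R_grid=R_grid, sigma_grid=sigma_grid, probabilities=P, fixed=fixed)
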