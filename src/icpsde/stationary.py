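"""Stationary (steady-state) distribution of the stochastic pressure model.

At steady state the Fokker–Planck equation for the stochastic logistic
pressure process has the zero-flux solution

    f(p) ∝ exp( ∫ 2·drift(p)/diffusion(p)² dp ) / diffusion(p)²
         ∝ p^(shape−1) · exp(−rate·p),

a gamma density with

    shape = 2(R·I + p_b)/(R·E·σ²) − 1,
    rate  = 2/(R·E·σ²)            (per mmHg),

which exists (shape > 0) precisely when σ² < 2(R·I + p_b)/(R·E).  Its
mean,

    μ = shape/rate = (R·I + p_b) − R·E·σ²/2,

is the deterministic (Davson) equilibrium lowered by a noise-induced
correction: fluctuations in CSF inflow *reduce* the average
steady-state ICP, and they dampen the sensitivity of that average to
the outflow resistance, ∂μ/∂R = I − σ²E/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DomainError, NoStationaryDistribution
from .model import CSFModelParams, deterministic_equilibrium

__all__ = [
    "StationaryGamma",
    "stationary_existence_bound",
    "stationary_distribution",
    "stationary_mean",
    "mean_sensitivity_to_R",
    "stationary_pdf",
]


@dataclass(frozen=True)
class StationaryGamma:
    """Gamma law of the stationary ICP, in shape/rate parameterisation.

    ``scale = 1/rate`` (mmHg) is the conversion to scipy's
    parameterisation; ``mean = shape/rate`` and
    ``variance = shape/rate²``.
    """

    shape: float  # dimensionless, > 0
    rate: float  # mmHg^-1, > 0

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.rate <= 0:
            raise DomainError("StationaryGamma requires shape > 0 and rate > 0")

    @property
    def scale(self) -> float:
        return 1.0 / self.rate

    @property
    def mean(self) -> float:
        """Mean ICP, mmHg."""
        return self.shape / self.rate

    @property
    def variance(self) -> float:
        """ICP variance, mmHg²."""
        return self.shape / self.rate**2

    @property
    def dist(self):
        """Frozen ``scipy.stats.gamma`` distribution."""
        return stats.gamma(a=self.shape, scale=self.scale)


def stationary_existence_bound(params: CSFModelParams) -> float:
    """Upper bound on σ² for a stationary law to exist, (mL/min)².

    Returns ``2(R·I + p_b)/(R·E)``; the stationary gamma exists iff
    ``sigma² < bound`` (strictly).
    """
    return 2.0 * deterministic_equilibrium(params) / (params.R * params.E)


def stationary_distribution(params: CSFModelParams) -> StationaryGamma:
    """Stationary gamma law of the ICP.

    Raises
    ------
    NoStationaryDistribution
        If ``sigma = 0`` (degenerate point mass — use
        :func:`icpsde.model.deterministic_equilibrium`) or if the noise
        is too strong, ``sigma² >= 2(R·I + p_b)/(R·E)``.
    """
    if params.sigma == 0:
        raise NoStationaryDistribution(
            "sigma = 0: the stationary law degenerates to a point mass at the "
            "deterministic equilibrium; use deterministic_equilibrium()"
        )
    bound = stationary_existence_bound(params)
    s2 = params.sigma**2
    if s2 >= bound:
        raise NoStationaryDistribution(
            f"no stationary distribution: sigma^2 = {s2:g} >= "
            f"2(RI+p_b)/(RE) = {bound:g} (mL/min)^2"
        )
    re_s2 = params.R * params.E * s2
    shape = 2.0 * deterministic_equilibrium(params) / re_s2 - 1.0
    rate = 2.0 / re_s2
    return StationaryGamma(shape=shape, rate=rate)


def stationary_mean(params: CSFModelParams) -> float:
    """Mean steady-state ICP, μ = (R·I + p_b) − R·E·σ²/2, mmHg.

    Strictly decreasing in σ².  Raises like
    :func:`stationary_distribution` when no stationary law exists
    (``sigma = 0`` returns the deterministic equilibrium limit is *not*
    taken here; the degenerate case signals).
    """
    return stationary_distribution(params).mean


def mean_sensitivity_to_R(params: CSFModelParams) -> float:
    """∂μ/∂R = I − σ²E/2, mmHg per (mmHg·mL⁻¹·min).

    Positive — the average ICP rises with outflow resistance — iff
    σ²E/2 < I; stronger inflow noise dampens the effect of R.
    """
    return params.I - params.sigma**2 * params.E / 2.0


def stationary_pdf(p, dist: StationaryGamma):
    """Stationary gamma density at pressure ``p`` (> 0 mmHg), mmHg⁻¹."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0):
        raise DomainError("stationary_pdf requires p > 0 mmHg")
    out = dist.dist.pdf(p)
    return out if out.ndim else float(out)
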