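"""Parameter model and deterministic CSF pressure dynamics.

The model describes intracranial pressure (ICP) ``p(t)`` during a
constant-rate infusion study.  Fluid enters the cerebrospinal space at
rate ``I`` (external infusion plus CSF formation, mL/min) and is either
stored in the compliant CSF space or reabsorbed into the sagittal
sinuses against an outflow resistance ``R`` (mmHg·mL⁻¹·min).  The
compliance shrinks hyperbolically as pressure rises,

    C(p) = 1 / (E · (p − p0_ref)),

with elastance ``E`` (mL⁻¹) and reference pressure ``p0_ref`` fixed at
0 mmHg.  Balancing formation, storage and reabsorption yields a
logistic (Verhulst-type) ordinary differential equation for the
pressure,

    dp/dt = alpha·p − beta·p²,   alpha = E(I + p_b/R),  beta = E/R,

whose equilibrium ``alpha/beta = R·I + p_b`` is the Davson relation:
baseline pressure plus resistance times inflow.  The stochastic
extension with multiplicative noise on the inflow rate lives in
:mod:`icpsde.sde`.

Units are fixed package-wide — minutes, mmHg, mL — and every operation
documents them; there is no unit-conversion layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError, ParameterError

__all__ = [
    "CSFModelParams",
    "DerivedCoefficients",
    "DEFAULT_PARAMS",
    "validate_params",
    "default_sigma",
    "compliance",
    "drift",
    "diffusion_coefficient",
    "deterministic_solution",
    "deterministic_equilibrium",
]

#: Names (and order) of the serialisable parameter fields.
PARAM_KEYS = ("E", "R", "p_b", "I", "sigma")


@dataclass(frozen=True)
class CSFModelParams:
    """Physiological parameters of the stochastic CSF pressure model.

    Attributes
    ----------
    E : float
        Cerebral elastance, mL⁻¹.  Must be positive.
    R : float
        Resistance to CSF outflow/reabsorption, mmHg·mL⁻¹·min.
        Must be positive.
    p_b : float
        Baseline pressure, mmHg.  Non-negative.
    I : float
        Constant infusion / CSF formation rate, mL·min⁻¹.  Non-negative.
    sigma : float
        Intensity of the fluctuations in the inflow rate, mL·min⁻¹.
        Non-negative; ``sigma = 0`` is the deterministic special case.
    p0_ref : float
        Reference pressure of the compliance law, mmHg.  Fixed at 0; the
        field is reserved so that a future nonzero-reference extension
        does not break serialised configurations.
    """

    E: float
    R: float
    p_b: float
    I: float
    sigma: float
    p0_ref: float = 0.0

    def __post_init__(self) -> None:
        validate_params(self)

    # -- derived coefficients -------------------------------------------------

    @property
    def alpha(self) -> float:
        """Logistic growth rate E·(I + p_b/R), min⁻¹."""
        return self.E * (self.I + self.p_b / self.R)

    @property
    def beta(self) -> float:
        """Logistic saturation coefficient E/R, mmHg⁻¹·min⁻¹."""
        return self.E / self.R

    @property
    def noise_amp(self) -> float:
        """Multiplicative noise rate sigma·E, min⁻¹."""
        return self.sigma * self.E

    def derived(self) -> "DerivedCoefficients":
        return DerivedCoefficients(self.alpha, self.beta, self.noise_amp)

    # -- serialisation --------------------------------------------------------

    def to_dict(self) -> dict:
        """Flat key/value form with exactly the keys E, R, p_b, I, sigma."""
        return {k: float(getattr(self, k)) for k in PARAM_KEYS}

    @classmethod
    def from_dict(cls, d: dict) -> "CSFModelParams":
        unknown = set(d) - set(PARAM_KEYS)
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_KEYS) - set(d)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(d[k]) for k in PARAM_KEYS})

    def replace(self, **changes) -> "CSFModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients of the logistic form dp = (alpha·p − beta·p²)dt + noise_amp·p·dW.

    ``alpha/beta`` equals the deterministic equilibrium ``R·I + p_b``
    exactly, by algebra.
    """

    alpha: float  # min^-1
    beta: float  # mmHg^-1 min^-1
    noise_amp: float  # min^-1


def validate_params(params: CSFModelParams) -> CSFModelParams:
    """Validate a parameter set, returning it unchanged.

    Raises
    ------
    ParameterError
        Naming the offending field, for non-positive ``E`` or ``R``,
        negative ``I``, ``sigma`` or ``p_b``, or nonzero ``p0_ref``.
    """
    for name in ("E", "R", "p_b", "I", "sigma", "p0_ref"):
        v = getattr(params, name)
        if not np.isfinite(v):
            raise ParameterError(f"{name} must be finite, got {v!r}")
    if params.E <= 0:
        raise ParameterError(f"E must be > 0 (mL^-1), got {params.E}")
    if params.R <= 0:
        raise ParameterError(f"R must be > 0 (mmHg mL^-1 min), got {params.R}")
    if params.p_b < 0:
        raise ParameterError(f"p_b must be >= 0 (mmHg), got {params.p_b}")
    if params.I < 0:
        raise ParameterError(f"I must be >= 0 (mL/min), got {params.I}")
    if params.sigma < 0:
        raise ParameterError(f"sigma must be >= 0 (mL/min), got {params.sigma}")
    if params.p0_ref != 0.0:
        raise ParameterError(
            f"p0_ref must be 0 (the nonzero reference-pressure case is not "
            f"supported), got {params.p0_ref}"
        )
    return params


def default_sigma(I: float, fraction: float = 0.33) -> float:
    """Default noise intensity: a set fraction of the inflow rate, rounded.

    The fluctuations in CSF formation are taken to be roughly one third
    of the mean inflow, so ``sigma = round(0.33·I, 1)`` mL/min — 0.5
    mL/min at the reference infusion rate of 1.5 mL/min.
    """
    return round(fraction * I, 1)


#: Reference parameter set from clinical infusion studies:
#: E = 0.15 mL^-1, R = 7 mmHg mL^-1 min, p_b = 8 mmHg, I = 1.5 mL/min,
#: sigma = 0.33*I rounded = 0.5 mL/min.
DEFAULT_PARAMS = CSFModelParams(E=0.15, R=7.0, p_b=8.0, I=1.5, sigma=default_sigma(1.5))


def compliance(p, params: CSFModelParams):
    """Cerebrospinal compliance C(p) = 1/(E·(p − p0_ref)), mL·mmHg⁻¹.

    Strictly decreasing in ``p``; defined for ``p > p0_ref`` (= 0).
    Accepts scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= params.p0_ref):
        raise DomainError("compliance requires p > p0_ref (= 0 mmHg)")
    out = 1.0 / (params.E * (p - params.p0_ref))
    return out if out.ndim else float(out)


def drift(p, params: CSFModelParams):
    """Drift field of the pressure SDE, mmHg·min⁻¹.

    ``E·p·I − E·p·(p − p_b)/R = alpha·p − beta·p²``; zero at ``p = 0``
    and at the equilibrium ``p = R·I + p_b``.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("drift requires p >= 0")
    out = params.alpha * p - params.beta * p * p
    return out if out.ndim else float(out)


def diffusion_coefficient(p, params: CSFModelParams):
    """Diffusion amplitude sigma·E·p of the pressure SDE, mmHg·min⁻¹ per
    unit white noise.  Linear in ``p`` and non-negative."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("diffusion_coefficient requires p >= 0")
    out = params.noise_amp * p
    return out if out.ndim else float(out)


def deterministic_solution(t, p_init: float, params: CSFModelParams):
    """Closed-form logistic solution of the noise-free pressure equation.

    For ``dp/dt = alpha·p − beta·p²`` with ``p(0) = p_init > 0``,

        p(t) = alpha / (beta + (alpha/p_init − beta)·exp(−alpha·t)),

    which approaches the equilibrium ``R·I + p_b`` monotonically.  The
    form above is overflow-safe for large ``t`` (``sigma`` is ignored).
    """
    t = np.asarray(t, dtype=float)
    if p_init <= 0:
        raise DomainError(f"p_init must be > 0 mmHg, got {p_init}")
    if np.any(t < 0):
        raise DomainError("t must be >= 0")
    a, b = params.alpha, params.beta
    if a == 0.0:  # I = 0 and p_b = 0: pure decay dp/dt = -beta p^2
        out = p_init / (1.0 + p_init * b * t)
    else:
        out = a / (b + (a / p_init - b) * np.exp(-a * t))
    return out if out.ndim else float(out)


def deterministic_equilibrium(params: CSFModelParams) -> float:
    """Steady state of the noise-free model: R·I + p_b (mmHg).

    Coincides with Davson's relation — baseline pressure plus outflow
    resistance times inflow — and equals ``alpha/beta`` exactly.
    """
    return params.R * params.I + params.p_b
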