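"""Synthetic constant-rate infusion recordings.

Emulates the noisy ICP trace of a clinical infusion study: a baseline
phase with no external infusion (the pressure settles near the baseline
``p_b``) followed by a constant-rate infusion phase (default 1.5
mL/min) during which the pressure rises logistically toward
``R·I + p_b`` while fluctuating with the multiplicative inflow noise.
The trace is simulated with the positivity-preserving log-Euler scheme
on a fine internal grid and resampled at the protocol's sampling
interval, yielding a stand-in for a noisy bedside recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError
from .model import CSFModelParams, DEFAULT_PARAMS
from .sde import ICPTrajectory, TimeGrid, _log_euler_paths

__all__ = ["RecordingProtocol", "synth_infusion_recording"]

#: Internal simulation step, minutes (refined to divide the sampling interval).
_BASE_DT = 1e-2


@dataclass(frozen=True)
class RecordingProtocol:
    """Protocol of a synthetic infusion study.

    Defaults: 10 min baseline, 45 min infusion at 1.5 mL/min, sampled
    every 0.1 min (6 s), at the reference physiological parameters.
    """

    baseline_duration: float = 10.0  # min
    infusion_duration: float = 45.0  # min
    infusion_rate: float = 1.5  # mL/min
    sampling_interval: float = 0.1  # min
    params: CSFModelParams = field(default_factory=lambda: DEFAULT_PARAMS)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_duration <= 0 or self.infusion_duration <= 0:
            raise DomainError("phase durations must be positive")
        if self.infusion_rate < 0:
            raise DomainError("infusion_rate must be >= 0")
        if not (0 < self.sampling_interval <= min(self.baseline_duration,
                                                  self.infusion_duration)):
            raise DomainError(
                "sampling_interval must be positive and no longer than either phase"
            )


def synth_infusion_recording(protocol: RecordingProtocol) -> ICPTrajectory:
    """Simulate a two-phase infusion recording (baseline then infusion).

    One continuous Brownian realisation drives both phases; the
    baseline phase uses ``I = 0`` and the infusion phase the protocol
    rate.  The result is resampled at ``sampling_interval`` and starts
    at the baseline pressure ``p_b``.
    """
    params = protocol.params
    # internal step: an integer fraction of the sampling interval, <= _BASE_DT
    refine = max(1, int(np.ceil(protocol.sampling_interval / _BASE_DT)))
    dt = protocol.sampling_interval / refine
    n_base = int(round(protocol.baseline_duration / dt))
    n_inf = int(round(protocol.infusion_duration / dt))
    rng = np.random.default_rng(int(protocol.seed))
    dW = rng.standard_normal(n_base + n_inf) * np.sqrt(dt)

    steps = np.full(n_base, dt)
    p_base = _log_euler_paths(params.replace(I=0.0), steps, dW[None, :n_base],
                              params.p_b)[0]
    steps = np.full(n_inf, dt)
    infusion_params = params.replace(I=protocol.infusion_rate)
    p_inf = _log_euler_paths(infusion_params, steps, dW[None, n_base:],
                             p_base[-1])[0]
    p = np.concatenate([p_base, p_inf[1:]])
    t = np.arange(p.size) * dt
    # resample at the protocol's sampling interval
    keep = slice(None, None, refine)
    grid = TimeGrid(t[keep])
    return ICPTrajectory(grid=grid, p=p[keep], scheme="log-euler",
                         seed=protocol.seed, params=infusion_params)
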