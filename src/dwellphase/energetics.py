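"""Energy-barrier inference from dwell-time changes (Kramers theory).

The escape from a channel conformation is modelled as thermally
activated barrier crossing.  The Kramers escape rate over a 1-D
potential landscape U(x) with well at a and barrier top at b is

    r = D / (2 pi k_B T) * sqrt(U''(a) U''(b)) * exp(-(U(b) - U(a)) / k_B T)

Since the mean dwell-time is the inverse escape rate (tau ~ 1/r), and
assuming modulator binding leaves the well/barrier curvatures unchanged,
the change of the barrier height between two conditions reduces to

    Delta(U(b) - U(a)) = k_B T * ln(tau_condition / tau_control),

so a lengthened dwell-time maps to a raised escape barrier.  Only
barrier *changes* are accessible this way; the absolute potential
reference is unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.constants import k as BOLTZMANN_J_PER_K

__all__ = [
    "KramersParams",
    "BarrierChange",
    "kramers_rate",
    "barrier_change",
    "DEFAULT_TEMPERATURE_K",
]

DEFAULT_TEMPERATURE_K = 295.0  # room-temperature recording


@dataclass
class KramersParams:
    """Parameters of the Kramers escape problem.

    D : diffusion coefficient along the reaction coordinate
        (units consistent with the curvatures; r comes out in the
        inverse time unit implied by D).
    curvature_a, curvature_b : |U''| at the well bottom and barrier top (J
        per squared reaction-coordinate unit).
    barrier : barrier height U(b) - U(a) in J.
    temperature : absolute temperature in K.
    """

    D: float
    curvature_a: float
    curvature_b: float
    barrier: float
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.D <= 0 or self.curvature_a <= 0 or self.curvature_b <= 0:
            raise ValueError("D and curvatures must be positive")
        if self.barrier < 0:
            raise ValueError("barrier height must be non-negative")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class BarrierChange:
    """Change of an escape barrier inferred from a dwell-time ratio."""

    delta_kbt: float  # Delta(U(b)-U(a)) in units of k_B T
    delta_joule: float
    tau_condition_ms: float
    tau_control_ms: float
    temperature: float


def kramers_rate(p: KramersParams) -> float:
    """Kramers escape rate for the given landscape parameters."""
    kbt = BOLTZMANN_J_PER_K * p.temperature
    return (
        p.D / (2.0 * math.pi * kbt)
        * math.sqrt(p.curvature_a * p.curvature_b)
        * math.exp(-p.barrier / kbt)
    )


def barrier_change(
    tau_condition_ms: float,
    tau_control_ms: float,
    temperature: float = DEFAULT_TEMPERATURE_K,
) -> BarrierChange:
    """Barrier-height change from the ratio of mean dwell-times.

    Positive when the dwell-time lengthened (state stabilized).  The
    curvature prefactor cancels under the constant-steepness assumption,
    leaving Delta = k_B T ln(tau_condition / tau_control).
    """
    if tau_condition_ms <= 0 or tau_control_ms <= 0:
        raise ValueError("dwell-times must be positive")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta_kbt = math.log(tau_condition_ms / tau_control_ms)
    return BarrierChange(
        delta_kbt=delta_kbt,
        delta_joule=delta_kbt * BOLTZMANN_J_PER_K * temperature,
        tau_condition_ms=tau_condition_ms,
        tau_control_ms=tau_control_ms,
        temperature=temperature,
    )
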