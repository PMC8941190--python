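"""Single-cable reduction of a dendritic branch and the location-dependent
decay-and-delay propagation model.

A branch is an ordered distal-to-proximal chain of cylindrical sections.  The
reduction sums a per-section electrotonic length and a per-section membrane
time constant:

    lambda = sum_j sqrt(R_m,j * d_j / (4 R_a,j))     [um]
    tau    = sum_j R_m,j * C_m,j                     [ms]

Note this is a deliberate per-section summation convention: the total time
constant grows with the number of sections, unlike the classical uniform-cable
R_m*C_m.  It is kept because the downstream delay model treats tau purely as a
fitted scale absorbed into the dimensionless constant beta.

An electrotonic signal entering at distance x from the proximal thresholding
point arrives as

    V_o(t) = alpha * exp(-x/lambda) * V_i(t - beta * tau * x / (2*pi)),

with alpha (decay scale) and beta (delay scale) fitted per branch from
single-synapse peak decays and peak-time lags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SimulationClock, VoltageTrace

__all__ = [
    "DendriteSection",
    "BranchCable",
    "PropagationParams",
    "axial_resistance_megaohm",
    "effective_length",
    "total_time_constant",
    "propagation_delay_ms",
    "propagate",
    "fit_propagation",
    "peak_decay_and_delay",
]


@dataclass(frozen=True)
class DendriteSection:
    """One cylindrical section: geometry in um, passive constants in
    Ohm*cm^2 (R_m), Ohm*cm (R_a) and uF/cm^2 (C_m)."""

    length: float
    diameter: float
    r_m: float = 10_000.0
    r_a: float = 100.0
    c_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("length", "diameter", "r_m", "r_a", "c_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"section {name} must be positive")

    @property
    def lambda_um(self) -> float:
        """Electrotonic length contribution sqrt(R_m d / (4 R_a)) in um."""
        d_cm = self.diameter * 1e-4
        lam_cm = math.sqrt((self.r_m / self.r_a) * d_cm / 4.0)
        return lam_cm * 1e4

    @property
    def tau_ms(self) -> float:
        """Membrane time-constant contribution R_m*C_m in ms."""
        return self.r_m * self.c_m * 1e-3  # Ohm*cm^2 * uF/cm^2 = 1e-3 ms... see note

    # Unit note: R_m [Ohm cm^2] * C_m [uF/cm^2] = 1e-6 F*Ohm = 1e-6 s = 1e-3 ms
    # per unit product, i.e. 10_000 * 1 -> 10 ms.


@dataclass(frozen=True)
class BranchCable:
    """Ordered distal-to-proximal sequence of sections forming one branch."""

    sections: tuple
    branch_id: str = "branch"

    def __post_init__(self) -> None:
        if len(self.sections) == 0:
            raise ValueError("a branch cable needs at least one section")
        object.__setattr__(self, "sections", tuple(self.sections))

    @property
    def lambda_total(self) -> float:
        return sum(s.lambda_um for s in self.sections)

    @property
    def tau_total(self) -> float:
        return sum(s.tau_ms for s in self.sections)

    @property
    def length(self) -> float:
        """Physical branch length in um."""
        return sum(s.length for s in self.sections)


def effective_length(cable: BranchCable) -> float:
    """Total effective (electrotonic) length of the branch in um."""
    return cable.lambda_total


def total_time_constant(cable: BranchCable) -> float:
    """Total membrane time constant of the branch in ms."""
    return cable.tau_total


def axial_resistance_megaohm(length_um: float, diameter_um: float, r_a_ohm_cm: float) -> float:
    """Axial resistance of a cylinder, R_a * L / (pi r^2), in megaohms.

    With the spine-neck values (R_a = 1122 Ohm*cm, diameter 0.1 um, length
    0.35 um) this evaluates to 500 MOhm.
    """
    if length_um <= 0 or diameter_um <= 0 or r_a_ohm_cm <= 0:
        raise ValueError("cylinder dimensions and resistivity must be positive")
    length_cm = length_um * 1e-4
    radius_cm = diameter_um * 1e-4 / 2.0
    r_ohm = r_a_ohm_cm * length_cm / (math.pi * radius_cm**2)
    return r_ohm / 1e6


@dataclass(frozen=True)
class PropagationParams:
    """Fitted decay/delay scales of one branch plus its cable constants."""

    alpha: float
    beta: float
    lambda_total: float
    tau_total: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.lambda_total <= 0 or self.tau_total <= 0:
            raise ValueError("cable constants must be positive")

    @classmethod
    def for_cable(cls, cable: BranchCable, alpha: float, beta: float) -> "PropagationParams":
        return cls(alpha=alpha, beta=beta,
                   lambda_total=cable.lambda_total, tau_total=cable.tau_total)


def propagation_delay_ms(params: PropagationParams, x: float) -> float:
    """Propagation delay beta * tau * x / (2 pi) in ms for distance x (um)."""
    return params.beta * params.tau_total * x / (2.0 * math.pi)


def propagate(
    trace: VoltageTrace, x: float, params: PropagationParams, clock: SimulationClock | None = None
) -> VoltageTrace:
    """Attenuate and delay an electrotonic trace over distance ``x`` (um).

    The delay is rounded to the nearest clock sample (bit-reproducible at the
    fixed step); samples before the delayed start are zero.  ``trace`` must be
    electrotonic (relative to rest).
    """
    if x < 0:
        raise ValueError("propagation distance must be >= 0")
    clock = clock or trace.clock
    decay = params.alpha * math.exp(-x / params.lambda_total)
    shift = int(round(propagation_delay_ms(params, x) / clock.dt))
    out = np.zeros_like(trace.values)
    if shift == 0:
        out[:] = decay * trace.values
    elif shift < len(out):
        out[shift:] = decay * trace.values[: len(out) - shift]
    return VoltageTrace(out, clock)


def fit_propagation(
    x: Sequence[float],
    decay_ratio: Sequence[float],
    delay_ms: Sequence[float],
    lambda_total: float,
    tau_total: float,
) -> PropagationParams:
    """Fit alpha and beta from a single-synapse sweep.

    ``decay_ratio`` are peak-amplitude ratios (thresholding point / spine
    head) and ``delay_ms`` the peak-time lags, one per synapse distance
    ``x`` (um).  alpha is the log-linear least-squares fit of
    ``decay = alpha * exp(-x/lambda)`` with lambda fixed from the cable
    reduction; beta is the least-squares slope through the origin of delay
    against ``tau * x / (2 pi)``.
    """
    x = np.asarray(x, dtype=float)
    decay = np.asarray(decay_ratio, dtype=float)
    delay = np.asarray(delay_ms, dtype=float)
    if x.size == 0:
        raise ValueError("sweep is empty")
    if not (x.size == decay.size == delay.size):
        raise ValueError("sweep arrays must have equal length")
    if np.any(x <= 0):
        raise ValueError("sweep distances must be positive")
    if np.any(decay <= 0):
        raise ValueError("decay ratios must be positive (log-linear fit)")
    log_alpha = float(np.mean(np.log(decay) + x / lambda_total))
    u = tau_total * x / (2.0 * math.pi)
    beta = float(np.sum(delay * u) / np.sum(u * u))
    return PropagationParams(
        alpha=math.exp(log_alpha),
        beta=max(beta, 0.0),
        lambda_total=lambda_total,
        tau_total=tau_total,
    )


def peak_decay_and_delay(spine: VoltageTrace, arrived: VoltageTrace) -> tuple:
    """Peak-amplitude ratio and peak-time lag (ms) between an electrotonic
    spine trace and the corresponding trace at the thresholding point."""
    i_in = int(np.argmax(spine.values))
    i_out = int(np.argmax(arrived.values))
    peak_in = spine.values[i_in]
    if peak_in <= 0:
        raise ValueError("spine trace has no positive peak")
    ratio = float(arrived.values[i_out] / peak_in)
    lag = (i_out - i_in) * spine.clock.dt
    return ratio, float(lag)
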