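"""Hodgkin-Huxley somatic spiking mechanism with Na+, K+, Ca2+ and leak
currents, driven by the summed normalized branch outputs.

    C dV/dt = I - g_Na m^3 h (V-V_Na) - g_K n^4 (V-V_K)
                - g_Ca s^2 r (V-V_Ca) - g_L (V-V_L)
    dz/dt   = alpha_z(V) (1 - z) - beta_z(V) z,   z in {m, n, h, r, s}

The drive current is ``drive_gain`` (10 uA/cm^2 by default) times the summed
branch activation values.  Integration is fixed-step classical Runge-Kutta
at the simulation step (0.05 ms); removable singularities in the alpha_m,
alpha_n and alpha_s rate expressions are evaluated by their analytic limits
rather than an epsilon offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SimulationClock, VoltageTrace

__all__ = [
    "HHParams",
    "GateState",
    "rate_functions",
    "steady_state_gates",
    "membrane_currents",
    "integrate_soma",
    "detect_spikes",
]


@dataclass(frozen=True)
class HHParams:
    """Somatic conductances (mS/cm^2), reversal potentials (mV), capacitance
    (uF/cm^2) and the drive gain (uA/cm^2 per unit of summed branch output)."""

    g_na: float = 120.0
    g_k: float = 36.0
    g_ca: float = 7.0
    g_l: float = 0.1
    v_na: float = 45.0
    v_k: float = -75.0
    v_ca: float = 90.0
    v_l: float = -70.0
    c: float = 1.0
    drive_gain: float = 10.0

    def __post_init__(self) -> None:
        for name in ("g_na", "g_k", "g_ca", "g_l"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.c <= 0:
            raise ValueError("capacitance must be positive")


@dataclass
class GateState:
    """Gating variables, each in [0, 1]."""

    m: float
    n: float
    h: float
    r: float
    s: float

    def as_array(self) -> np.ndarray:
        return np.array([self.m, self.n, self.h, self.r, self.s], dtype=float)


def _lin_over_expm1(u, k):
    """u / (exp(u/k) - 1) with the analytic limit k at u -> 0."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-7
    safe = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        out = np.where(small, k - u / 2.0, safe / np.expm1(safe / k))
    return out


def rate_functions(v):
    """The ten gating rate expressions (ms^-1) at membrane potential v (mV).

    Returns a dict {gate: (alpha, beta)} for gates m, n, h, r, s.
    """
    v = np.asarray(v, dtype=float)
    am = 0.1 * _lin_over_expm1(-v - 45.0, 10.0)
    bm = 4.0 * np.exp((-v - 70.0) / 18.0)
    an = 0.01 * _lin_over_expm1(-v - 60.0, 10.0)
    bn = 0.125 * np.exp((-v - 70.0) / 80.0)
    ah = 0.07 * np.exp((-v - 70.0) / 30.0)
    bh = 1.0 / (np.exp((-v - 40.0) / 10.0) + 1.0)
    ar = 0.000457 * np.exp((-v - 13.0) / 50.0)
    br = 0.0065 / (np.exp((-v - 15.0) / 38.0) + 1.0)
    as_ = 0.055 * _lin_over_expm1(-v - 27.0, 3.8)
    bs = 0.094 * np.exp((-v - 75.0) / 17.0)
    return {"m": (am, bm), "n": (an, bn), "h": (ah, bh), "r": (ar, br), "s": (as_, bs)}


def steady_state_gates(v: float) -> GateState:
    """Gate steady states z_inf(v) = alpha/(alpha+beta)."""
    rates = rate_functions(v)
    vals = {z: float(a / (a + b)) for z, (a, b) in rates.items()}
    return GateState(**vals)


def membrane_currents(v, gates: np.ndarray, params: HHParams):
    """The four ionic current terms (uA/cm^2), outward positive."""
    m, n, h, r, s = gates
    i_na = params.g_na * m**3 * h * (v - params.v_na)
    i_k = params.g_k * n**4 * (v - params.v_k)
    i_ca = params.g_ca * s**2 * r * (v - params.v_ca)
    i_l = params.g_l * (v - params.v_l)
    return i_na, i_k, i_ca, i_l


def _scalar_rates(v: float) -> tuple:
    """Scalar fast path of :func:`rate_functions` for the inner RK4 loop."""
    import math

    def lin(u, k):
        if abs(u) < 1e-7:
            return k - u / 2.0
        return u / math.expm1(u / k)

    am = 0.1 * lin(-v - 45.0, 10.0)
    bm = 4.0 * math.exp((-v - 70.0) / 18.0)
    an = 0.01 * lin(-v - 60.0, 10.0)
    bn = 0.125 * math.exp((-v - 70.0) / 80.0)
    ah = 0.07 * math.exp((-v - 70.0) / 30.0)
    bh = 1.0 / (math.exp((-v - 40.0) / 10.0) + 1.0)
    ar = 0.000457 * math.exp((-v - 13.0) / 50.0)
    br = 0.0065 / (math.exp((-v - 15.0) / 38.0) + 1.0)
    as_ = 0.055 * lin(-v - 27.0, 3.8)
    bs = 0.094 * math.exp((-v - 75.0) / 17.0)
    return am, bm, an, bn, ah, bh, ar, br, as_, bs


def _derivatives(state, i_drive: float, params: HHParams):
    v, m, n, h, r, s = state
    i_na = params.g_na * m * m * m * h * (v - params.v_na)
    i_k = params.g_k * n**4 * (v - params.v_k)
    i_ca = params.g_ca * s * s * r * (v - params.v_ca)
    i_l = params.g_l * (v - params.v_l)
    dv = (i_drive - i_na - i_k - i_ca - i_l) / params.c
    am, bm, an, bn, ah, bh, ar, br, as_, bs = _scalar_rates(v)
    return np.array(
        [
            dv,
            am * (1.0 - m) - bm * m,
            an * (1.0 - n) - bn * n,
            ah * (1.0 - h) - bh * h,
            ar * (1.0 - r) - br * r,
            as_ * (1.0 - s) - bs * s,
        ]
    )


def integrate_soma(
    drive,
    params: HHParams,
    clock: SimulationClock,
    v0: float = -70.0,
    gates0: GateState | None = None,
    spike_threshold: float = 0.0,
    refractory: float = 2.0,
):
    """Fixed-step RK4 integration of the somatic membrane equation.

    ``drive`` is the summed branch activation sampled on the clock (the
    injected current is ``drive_gain * drive``).  Returns the voltage trace,
    the gate history (n_samples x 5 array, columns m, n, h, r, s) and the
    spike times found by :func:`detect_spikes`.

    Gates are clipped to [0, 1] after each step (the exact dynamics keep them
    inside; clipping only removes sub-ulp excursions).  A non-finite state
    aborts with an error, which indicates the step is too large.
    """
    drive = np.asarray(drive, dtype=float)
    if drive.shape != (clock.n_samples,):
        raise ValueError("drive must be sampled on the clock")
    if gates0 is None:
        gates0 = steady_state_gates(v0)
    state = np.empty(6)
    state[0] = v0
    state[1:] = gates0.as_array()
    if not np.all(np.isfinite(state)):
        raise ValueError("initial state must be finite")

    dt = clock.dt
    n = clock.n_samples
    v_hist = np.empty(n)
    gate_hist = np.empty((n, 5))
    v_hist[0] = state[0]
    gate_hist[0] = state[1:]
    for i in range(1, n):
        # Drive held at its left-sample value across the step: the drive is a
        # sampled signal, not a closed form, so midpoint values would be
        # interpolation artifacts.
        i_drive = params.drive_gain * drive[i - 1]
        k1 = _derivatives(state, i_drive, params)
        k2 = _derivatives(state + 0.5 * dt * k1, i_drive, params)
        k3 = _derivatives(state + 0.5 * dt * k2, i_drive, params)
        k4 = _derivatives(state + dt * k3, i_drive, params)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        state[1:] = np.clip(state[1:], 0.0, 1.0)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(
                f"soma integration diverged at t = {i * dt:.3f} ms (dt too large?)"
            )
        v_hist[i] = state[0]
        gate_hist[i] = state[1:]
    trace = VoltageTrace(v_hist, clock)
    spikes = detect_spikes(trace, threshold=spike_threshold, refractory=refractory)
    return trace, gate_hist, spikes


def detect_spikes(
    trace: VoltageTrace, threshold: float = 0.0, refractory: float = 2.0
) -> np.ndarray:
    """Times (ms) of upward threshold crossings separated by >= refractory."""
    v = trace.values
    crossings = np.flatnonzero((v[:-1] <= threshold) & (v[1:] > threshold)) + 1
    times = []
    last = -np.inf
    for idx in crossings:
        t = idx * trace.clock.dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)
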