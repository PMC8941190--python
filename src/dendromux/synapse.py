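"""Synaptic conductance kinetics, Poisson activation trains, spine-head EPSP
traces, and the stimulation-protocol ensembles.

AMPA- and NMDA-receptor conductances are peak-normalized double exponentials;
the NMDA waveform additionally carries the voltage-dependent extracellular
Mg2+ block.  Spine-head voltage traces are synthesized directly as a
rest-plus-double-exponential template calibrated to a stated single-event
peak depolarization and full width at half maximum, so the package is fully
self-contained: no multicompartment simulator is needed to produce inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .core import SimulationClock, VoltageTrace

__all__ = [
    "AMPAKinetics",
    "NMDAKinetics",
    "SpikeTrain",
    "SynapseSite",
    "EPSPShape",
    "StimulationProtocol",
    "PLACEMENT_WINDOWS",
    "ampa_conductance",
    "nmda_conductance",
    "mg_block",
    "generate_spike_train",
    "spine_epsp_trace",
    "make_protocol",
    "enumerate_input_categories",
    "run_allocation",
]


def _double_exp_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the maximum of exp(-t/tau_decay) - exp(-t/tau_rise)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)) * math.log(
        tau_decay / tau_rise
    )


def _double_exp_alpha(tau_rise: float, tau_decay: float) -> float:
    """Normalization factor so the double-exponential peak equals 1."""
    tp = _double_exp_peak_time(tau_rise, tau_decay)
    peak = math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise)
    return 1.0 / peak


def _validate_taus(tau_rise: float, tau_decay: float) -> None:
    if tau_rise <= 0 or tau_decay <= 0:
        raise ValueError("time constants must be positive")
    if tau_decay <= tau_rise:
        raise ValueError(
            "degenerate kinetics: decay constant must exceed rise constant "
            "(the alpha-function limit is not implemented)"
        )


@dataclass(frozen=True)
class AMPAKinetics:
    """AMPA-receptor double-exponential conductance parameters.

    Defaults: peak conductance 0.5 nS, rise 0.2 ms, decay 2 ms, reversal 0 mV.
    ``alpha`` is computed so the waveform maximum equals ``g_max``.
    """

    g_max: float = 0.5
    tau_rise: float = 0.2
    tau_decay: float = 2.0
    e_rev: float = 0.0

    def __post_init__(self) -> None:
        _validate_taus(self.tau_rise, self.tau_decay)

    @property
    def alpha(self) -> float:
        return _double_exp_alpha(self.tau_rise, self.tau_decay)


@dataclass(frozen=True)
class NMDAKinetics:
    """NMDA-receptor conductance parameters with extracellular Mg2+ block.

    Defaults: peak 0.16 nS, rise 2 ms, decay 86 ms, reversal -5 mV, [Mg2+] 1 mM.
    """

    g_max: float = 0.16
    tau_rise: float = 2.0
    tau_decay: float = 86.0
    e_rev: float = -5.0
    mg_out: float = 1.0

    def __post_init__(self) -> None:
        _validate_taus(self.tau_rise, self.tau_decay)
        if self.mg_out < 0:
            raise ValueError("extracellular Mg2+ concentration must be >= 0")

    @property
    def alpha(self) -> float:
        return _double_exp_alpha(self.tau_rise, self.tau_decay)


def ampa_conductance(t, onset: float, kin: AMPAKinetics = AMPAKinetics()):
    """AMPA conductance (nS) at times ``t`` (ms) for one activation at ``onset``.

    Zero before onset; peak-normalized double exponential afterwards, with
    global maximum ``kin.g_max``.
    """
    t = np.asarray(t, dtype=float)
    s = t - onset
    with np.errstate(invalid="ignore"):
        wave = np.where(
            s >= 0,
            np.exp(-np.maximum(s, 0.0) / kin.tau_decay)
            - np.exp(-np.maximum(s, 0.0) / kin.tau_rise),
            0.0,
        )
    return kin.g_max * kin.alpha * wave


def mg_block(v, mg_out: float = 1.0):
    """Voltage-dependent Mg2+ unblock factor, in (0, 1] for finite voltage."""
    v = np.asarray(v, dtype=float)
    return 1.0 / (1.0 + mg_out * np.exp(-0.062 * v) / 3.57)


def nmda_conductance(t, onset: float, v, kin: NMDAKinetics = NMDAKinetics()):
    """NMDA conductance (nS): peak-normalized double exponential times the
    Mg2+ unblock factor evaluated at membrane potential ``v`` (mV)."""
    t = np.asarray(t, dtype=float)
    s = t - onset
    wave = np.where(
        s >= 0,
        np.exp(-np.maximum(s, 0.0) / kin.tau_decay)
        - np.exp(-np.maximum(s, 0.0) / kin.tau_rise),
        0.0,
    )
    return kin.g_max * kin.alpha * wave * mg_block(v, kin.mg_out)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered synaptic activation times (ms) with the seed that produced them."""

    activation_times: tuple
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.activation_times)
        object.__setattr__(self, "activation_times", times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("activation times must be strictly increasing")
        if times and times[0] < 0:
            raise ValueError("activation times must be non-negative")


def generate_spike_train(
    mean_interval: float, duration: float, seed
) -> SpikeTrain:
    """Homogeneous Poisson activation train on [0, duration].

    Inter-activation intervals are exponential with the given mean (ms).
    Identical seeds give identical trains.  ``seed`` may be an int or a
    ``numpy.random.Generator``.
    """
    if mean_interval <= 0:
        raise ValueError("mean_interval must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = []
    t = rng.exponential(mean_interval)
    while t <= duration:
        times.append(t)
        t += rng.exponential(mean_interval)
    label = seed if isinstance(seed, int) else None
    return SpikeTrain(tuple(times), seed=label)


@dataclass(frozen=True)
class EPSPShape:
    """Summary statistics of the single-event spine-head EPSP.

    Defaults: 14.81 mV peak depolarization from a -70 mV rest and a 2.75 ms
    full width at half maximum, the combined AMPA/NMDA spine-head waveform.
    """

    peak_amplitude: float = 14.81
    half_width: float = 2.75
    rest: float = -70.0

    def __post_init__(self) -> None:
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")
        if self.half_width <= 0:
            raise ValueError("half_width must be positive")


# Rise:decay ratio of the EPSP voltage template.  Fixed to the 1:10 ratio of
# the AMPA conductance kinetics (0.2 ms / 2 ms); the template FWHM then fixes
# the absolute time scale uniquely.
_TEMPLATE_TAU_RATIO = 10.0


def _unit_double_exp_fwhm(tau_rise: float, tau_decay: float) -> float:
    """FWHM (ms) of the peak-normalized double exponential."""
    alpha = _double_exp_alpha(tau_rise, tau_decay)
    tp = _double_exp_peak_time(tau_rise, tau_decay)

    def g(t):
        return alpha * (math.exp(-t / tau_decay) - math.exp(-t / tau_rise)) - 0.5

    left = brentq(g, 1e-12, tp)
    hi = tp
    while g(hi) > 0:
        hi *= 2.0
    right = brentq(g, tp, hi)
    return right - left


def epsp_time_constants(shape: EPSPShape) -> tuple:
    """Solve for the (rise, decay) time constants of the EPSP template.

    The rise:decay ratio is held at 1:10 and both constants are scaled so the
    peak-normalized waveform has the requested FWHM; the waveform scales
    linearly in time, so the solve is a single division.
    """
    base_rise = 1.0
    base_decay = _TEMPLATE_TAU_RATIO
    base_fwhm = _unit_double_exp_fwhm(base_rise, base_decay)
    scale = shape.half_width / base_fwhm
    return base_rise * scale, base_decay * scale


def spine_epsp_trace(
    train: SpikeTrain,
    shape: EPSPShape,
    noise_sd: float,
    clock: SimulationClock,
    seed,
) -> VoltageTrace:
    """Spine-head voltage trace (absolute mV) for one synapse.

    Each activation adds a calibrated double-exponential depolarization whose
    single-event peak equals ``shape.peak_amplitude`` and whose FWHM equals
    ``shape.half_width``; events superpose linearly.  Gaussian noise with
    standard deviation ``noise_sd`` (mV) is added to the voltage template.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tau_rise, tau_decay = epsp_time_constants(shape)
    alpha = _double_exp_alpha(tau_rise, tau_decay)
    t = clock.times()
    v = np.full(clock.n_samples, shape.rest, dtype=float)
    for onset in train.activation_times:
        s = t - onset
        mask = s >= 0
        v[mask] += (
            shape.peak_amplitude
            * alpha
            * (np.exp(-s[mask] / tau_decay) - np.exp(-s[mask] / tau_rise))
        )
    if noise_sd > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return VoltageTrace(v, clock)


@dataclass(frozen=True)
class SynapseSite:
    """A synapse location on a branch.

    ``fraction`` is the position as a multiple of the branch length d,
    measured from the branch's proximal thresholding point; ``position`` is
    the same distance in micrometres.
    """

    branch_id: str
    fraction: float
    position: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("site fraction must lie in [0, 1]")
        if self.position < 0:
            raise ValueError("site position must be >= 0")


# Placement windows as fractions of the branch length d, measured from the
# thresholding point.  Segregated inputs span half or all of the branch;
# clustered inputs are confined to one quarter.
PLACEMENT_WINDOWS = {
    "segregated_whole": (0.01, 1.0),
    "segregated_proximal_half": (0.01, 0.5),
    "segregated_distal_half": (0.5, 1.0),
    "clustered_q1": (0.01, 0.25),
    "clustered_q2": (0.25, 0.5),
    "clustered_q3": (0.5, 0.75),
    "clustered_q4": (0.75, 1.0),
}

SYNAPSE_COUNTS = (3, 5, 7)


@dataclass
class StimulationProtocol:
    """Synapse placements plus per-synapse activation trains for one branch."""

    branch_id: str
    category: str
    sites: list
    trains: list
    seed: int
    duration_ms: float = 1000.0
    mean_interval_ms: float = 20.0
    noise_sd: float = 0.2

    @property
    def n_synapses(self) -> int:
        return len(self.sites)


def make_protocol(
    branch_length: float,
    n_synapses: int,
    category: str,
    seed: int,
    branch_id: str = "branch",
    duration_ms: float = 1000.0,
    mean_interval_ms: float = 20.0,
    noise_sd: float = 0.2,
) -> StimulationProtocol:
    """Place ``n_synapses`` uniformly inside the category's fractional window
    and attach an independent Poisson activation train (mean interval 20 ms by
    default) to each, with reproducible per-site sub-seeds."""
    if category not in PLACEMENT_WINDOWS:
        raise ValueError(
            f"unknown placement category {category!r}; "
            f"choose from {sorted(PLACEMENT_WINDOWS)}"
        )
    if n_synapses <= 0:
        raise ValueError("n_synapses must be positive")
    if branch_length <= 0:
        raise ValueError("branch_length must be positive")
    lo, hi = PLACEMENT_WINDOWS[category]
    ss = np.random.SeedSequence(seed)
    place_rng = np.random.default_rng(ss.spawn(1)[0])
    fractions = place_rng.uniform(lo, hi, size=n_synapses)
    sites = [
        SynapseSite(branch_id=branch_id, fraction=float(f), position=float(f) * branch_length)
        for f in fractions
    ]
    train_seeds = ss.spawn(n_synapses + 1)[1:]
    trains = [
        generate_spike_train(
            mean_interval_ms, duration_ms, np.random.default_rng(s)
        )
        for s in train_seeds
    ]
    return StimulationProtocol(
        branch_id=branch_id,
        category=category,
        sites=sites,
        trains=trains,
        seed=seed,
        duration_ms=duration_ms,
        mean_interval_ms=mean_interval_ms,
        noise_sd=noise_sd,
    )


def enumerate_input_categories():
    """All (placement category, synapse count) study conditions: 7 x 3 = 21."""
    return [
        (cat, n) for cat in PLACEMENT_WINDOWS for n in SYNAPSE_COUNTS
    ]


def run_allocation(mode: str = "per_branch") -> dict:
    """Simulation-run allocation over placement categories.

    ``per_branch`` (default): ten runs for segregated inputs along the whole
    branch and five for each remaining category, 40 runs per branch in total.
    ``per_count``: the same allocation applied at each synapse count
    separately (40 runs per count, 120 per branch) — the alternative reading
    of the run budget.
    """
    base = {
        cat: (10 if cat == "segregated_whole" else 5) for cat in PLACEMENT_WINDOWS
    }
    if mode == "per_branch":
        return base
    if mode == "per_count":
        return {
            (cat, n): runs for cat, runs in base.items() for n in SYNAPSE_COUNTS
        }
    raise ValueError("mode must be 'per_branch' or 'per_count'")
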