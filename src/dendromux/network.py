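"""Assembly of branch subunits into a multilayer-multiplexer neuron and the
full protocol-to-spikes simulation.

Each branch subunit integrates its own synaptic inputs: spine-head traces are
attenuated and delayed over their site distances, summed and normalized at
the proximal thresholding point (X1), and passed through the branch's dynamic
thresholding function with X2 equal to the number of active synapses.  A
child's thresholded output then travels through its parent's cable with the
parent's decay and delay but is *not* re-thresholded by the parent: the
parent acts as a multiplexer line, and the child's signal is linearly summed
with the parent's own output.  The summed signal arriving at the soma drives
a Hodgkin-Huxley spiking mechanism at 10 uA/cm^2 per unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np

from .cable import BranchCable, PropagationParams, propagate
from .core import NormalizationMap, SimulationClock, VoltageTrace
from .soma import HHParams, integrate_soma
from .synapse import EPSPShape, StimulationProtocol, spine_epsp_trace
from .threshold import ThresholdParams, threshold_transform

__all__ = [
    "BranchSubunit",
    "NeuronModel",
    "SimulationResult",
    "simulate",
    "compare_spike_trains",
]

SOMA = "soma"


@dataclass
class BranchSubunit:
    """One dendritic branch: cable geometry, fitted propagation scales and
    the branch's thresholding-function row.  ``parent`` is another branch id
    or ``"soma"`` for primary branches."""

    branch_id: str
    cable: BranchCable
    propagation: PropagationParams
    threshold: ThresholdParams
    parent: str = SOMA


@dataclass
class NeuronModel:
    """Tree of branch subunits plus the somatic spiking parameters."""

    subunits: Dict[str, BranchSubunit]
    soma: HHParams
    clock: SimulationClock
    nmap: NormalizationMap = field(default_factory=NormalizationMap)
    rest: float = -70.0
    epsp_shape: EPSPShape = field(default_factory=EPSPShape)

    def __post_init__(self) -> None:
        if not self.subunits:
            raise ValueError("a neuron model needs at least one subunit")
        self.validate_tree()

    def validate_tree(self) -> None:
        for bid, sub in self.subunits.items():
            if sub.branch_id != bid:
                raise ValueError(f"subunit key {bid!r} does not match its id")
            if sub.parent != SOMA and sub.parent not in self.subunits:
                raise ValueError(f"subunit {bid!r} has unknown parent {sub.parent!r}")
        # cycle check: walk each subunit to the soma
        for bid in self.subunits:
            seen = set()
            cur = bid
            while cur != SOMA:
                if cur in seen:
                    raise ValueError(f"cyclic topology involving {cur!r}")
                seen.add(cur)
                cur = self.subunits[cur].parent
        if not any(s.parent == SOMA for s in self.subunits.values()):
            raise ValueError("at least one primary subunit must attach to the soma")

    def children(self, branch_id: str) -> list:
        return [b for b, s in self.subunits.items() if s.parent == branch_id]


@dataclass
class SimulationResult:
    """Per-subunit thresholding-point traces (normalized), per-subunit f
    outputs, the somatic voltage trace and spike times, and the seeds used."""

    x1_traces: Dict[str, VoltageTrace]
    f_traces: Dict[str, VoltageTrace]
    soma_drive: VoltageTrace
    soma_trace: VoltageTrace
    soma_gates: np.ndarray
    spike_times: np.ndarray
    seeds: Dict[str, int]


def _branch_x1(
    model: NeuronModel,
    sub: BranchSubunit,
    protocol: StimulationProtocol,
    rng: np.random.Generator,
) -> VoltageTrace:
    """Normalized summation of the attenuated spine inputs of one branch."""
    clock = model.clock
    total = np.zeros(clock.n_samples)
    for site, train in zip(protocol.sites, protocol.trains):
        spine = spine_epsp_trace(
            train, model.epsp_shape, protocol.noise_sd, clock, rng
        )
        electro = VoltageTrace(spine.values - model.rest, clock)
        total += propagate(electro, site.position, sub.propagation).values
    return VoltageTrace(total / model.nmap.span, clock)


def simulate(
    model: NeuronModel,
    protocols: Dict[str, StimulationProtocol],
    seed: int = 0,
) -> SimulationResult:
    """Run the full neuron: leaf-to-root branch integration, multiplexed
    transfer through parent cables, and somatic Hodgkin-Huxley spiking.

    Branches without a protocol contribute no synaptic drive of their own
    (their f output is taken as zero rather than the regression intercept,
    since an inactive branch is physically silent) but still carry their
    children's multiplexed signals.
    """
    for bid in protocols:
        if bid not in model.subunits:
            raise ValueError(f"protocol refers to unknown branch {bid!r}")
    clock = model.clock
    ss = np.random.SeedSequence(seed)
    branch_order = sorted(model.subunits)  # deterministic rng assignment
    child_seeds = ss.spawn(len(branch_order))
    seeds = {bid: int(s.generate_state(1)[0] % (2**31)) for bid, s in zip(branch_order, child_seeds)}
    rngs = {bid: np.random.default_rng(s) for bid, s in zip(branch_order, child_seeds)}

    x1_traces: Dict[str, VoltageTrace] = {}
    f_traces: Dict[str, VoltageTrace] = {}
    zeros = np.zeros(clock.n_samples)

    for bid in branch_order:
        sub = model.subunits[bid]
        if bid in protocols:
            proto = protocols[bid]
            x1 = _branch_x1(model, sub, proto, rngs[bid])
            f = threshold_transform(x1.values, proto.n_synapses, sub.threshold)
        else:
            x1 = VoltageTrace(zeros.copy(), clock)
            f = zeros.copy()
        x1_traces[bid] = x1
        f_traces[bid] = VoltageTrace(np.asarray(f, dtype=float), clock)

    span = model.nmap.span

    def outgoing(bid: str) -> np.ndarray:
        """Normalized signal at the proximal end of branch ``bid``: its own f
        output plus each child's outgoing signal passed through this branch's
        cable (decay and delay over the full branch length, no re-threshold)."""
        sub = model.subunits[bid]
        total = f_traces[bid].values.copy()
        for child in model.children(bid):
            child_sig = outgoing(child)
            electro = VoltageTrace(child_sig * span, clock)
            arrived = propagate(electro, sub.cable.length, sub.propagation)
            total += arrived.values / span
        return total

    drive = np.zeros(clock.n_samples)
    for bid, sub in model.subunits.items():
        if sub.parent == SOMA:
            drive += outgoing(bid)
    drive = np.clip(drive, 0.0, None)
    drive_trace = VoltageTrace(drive, clock)

    soma_trace, gate_hist, spikes = integrate_soma(drive, model.soma, clock, v0=model.rest)
    return SimulationResult(
        x1_traces=x1_traces,
        f_traces=f_traces,
        soma_drive=drive_trace,
        soma_trace=soma_trace,
        soma_gates=gate_hist,
        spike_times=spikes,
        seeds=seeds,
    )


def compare_spike_trains(
    reference,
    predicted,
    duration: float,
    window: float = 200.0,
    stride: float = 50.0,
) -> float:
    """Squared correlation of windowed spike counts between two trains.

    Counts spikes of both trains in sliding windows of length ``window`` ms
    advanced by ``stride`` ms across [0, duration], and returns the squared
    Pearson correlation of the two count sequences.  If either count sequence
    has zero variance the comparison is undefined and NaN is returned.
    """
    if window > duration:
        raise ValueError("window must not exceed the duration")
    if stride <= 0:
        raise ValueError("stride must be positive")
    reference = np.sort(np.asarray(reference, dtype=float))
    predicted = np.sort(np.asarray(predicted, dtype=float))
    starts = np.arange(0.0, duration - window + 1e-9, stride)
    ref_counts = np.searchsorted(reference, starts + window) - np.searchsorted(reference, starts)
    pred_counts = np.searchsorted(predicted, starts + window) - np.searchsorted(predicted, starts)
    if np.var(ref_counts) == 0 or np.var(pred_counts) == 0:
        return float("nan")
    r = np.corrcoef(ref_counts, pred_counts)[0, 1]
    return float(r**2)
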