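"""A packaged three-level toy neuron: one primary, one secondary and one
tertiary branch in a chain to the soma.

The cables use the default passive constants (R_m = 10 000 Ohm*cm^2,
R_a = 100 Ohm*cm, C_m = 1 uF/cm^2) with plausible apical geometry; the
decay/delay scales alpha and beta are documented placeholders in the range a
per-branch single-synapse sweep would produce, and each branch carries its
registry thresholding row.  The fixture exists so every pipeline stage can be
exercised end to end without an external morphology.
"""

from __future__ import annotations

from .cable import BranchCable, DendriteSection, PropagationParams
from .core import NormalizationMap, SimulationClock
from .network import BranchSubunit, NeuronModel
from .soma import HHParams
from .threshold import load_registry

__all__ = ["make_toy_neuron", "TOY_GEOMETRY", "TOY_PROPAGATION"]

# length (um), diameter (um) per branch level
TOY_GEOMETRY = {
    "primary": (50.0, 2.0),
    "secondary": (120.0, 1.5),
    "tertiary": (140.0, 1.0),
}

# placeholder (alpha, beta): alpha below 1 reflects the spine-neck and shaft
# amplitude drop, beta gives sub-ms to few-ms delays over these lengths
TOY_PROPAGATION = {
    "primary": (0.95, 0.005),
    "secondary": (0.85, 0.005),
    "tertiary": (0.80, 0.005),
}

_PARENTS = {"primary": "soma", "secondary": "primary", "tertiary": "secondary"}


def make_toy_neuron(duration_ms: float = 1000.0, dt: float = 0.05) -> NeuronModel:
    """Three-subunit chain (tertiary -> secondary -> primary -> soma) with the
    packaged thresholding registry attached."""
    registry = load_registry()
    clock = SimulationClock(duration=duration_ms, dt=dt)
    subunits = {}
    for label, (length, diameter) in TOY_GEOMETRY.items():
        cable = BranchCable(
            (DendriteSection(length=length, diameter=diameter),), branch_id=label
        )
        alpha, beta = TOY_PROPAGATION[label]
        subunits[label] = BranchSubunit(
            branch_id=label,
            cable=cable,
            propagation=PropagationParams.for_cable(cable, alpha=alpha, beta=beta),
            threshold=registry[label],
            parent=_PARENTS[label],
        )
    return NeuronModel(
        subunits=subunits,
        soma=HHParams(),
        clock=clock,
        nmap=NormalizationMap(),
    )
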