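"""YAML model/protocol serialization and run manifests.

Model files name the subunits, their parent links, cable sections (inline or
via an SWC path), propagation scales and thresholding rows; protocol files
carry the stimulation configuration per branch.  Every stochastic CLI run
writes a JSON manifest recording the command, the configuration snapshot, all
seeds, the package version and digests of the files it read and wrote, so a
run can be reproduced bit-identically.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from typing import Dict, Optional

import yaml

from .cable import BranchCable, DendriteSection, PropagationParams
from .core import NormalizationMap, SimulationClock
from .network import BranchSubunit, NeuronModel
from .soma import HHParams
from .swc import read_swc, swc_to_cables
from .synapse import StimulationProtocol, make_protocol
from .threshold import ThresholdParams, load_registry

__all__ = [
    "load_model",
    "save_model",
    "load_protocols",
    "save_protocols",
    "write_manifest",
    "fit_result_to_dict",
]


def _cable_from_cfg(cfg: dict, branch_id: str) -> BranchCable:
    if "swc" in cfg:
        cables = swc_to_cables(read_swc(cfg["swc"]))
        index = int(cfg.get("swc_cable_index", 0))
        return cables[index]
    sections = tuple(
        DendriteSection(
            length=float(s["length"]),
            diameter=float(s["diameter"]),
            r_m=float(s.get("r_m", 10_000.0)),
            r_a=float(s.get("r_a", 100.0)),
            c_m=float(s.get("c_m", 1.0)),
        )
        for s in cfg["sections"]
    )
    return BranchCable(sections, branch_id=branch_id)


def _threshold_from_cfg(cfg, registry) -> ThresholdParams:
    if isinstance(cfg, str):
        return registry[cfg]
    return ThresholdParams(
        a=float(cfg["a"]), b=float(cfg["b"]), c=float(cfg["c"]), d=float(cfg["d"]),
        theta=None if cfg.get("theta") is None else float(cfg["theta"]),
        v_max=float(cfg["v_max"]),
        branch_label=str(cfg.get("branch_label", "")),
    )


def load_model(path) -> NeuronModel:
    """Build a NeuronModel from a YAML description."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    registry = load_registry()
    clock = SimulationClock(
        duration=float(cfg.get("duration_ms", 1000.0)),
        dt=float(cfg.get("dt_ms", 0.05)),
    )
    subunits: Dict[str, BranchSubunit] = {}
    for bid, sub_cfg in cfg["subunits"].items():
        cable = _cable_from_cfg(sub_cfg["cable"], bid)
        prop_cfg = sub_cfg["propagation"]
        propagation = PropagationParams.for_cable(
            cable, alpha=float(prop_cfg["alpha"]), beta=float(prop_cfg["beta"])
        )
        subunits[bid] = BranchSubunit(
            branch_id=bid,
            cable=cable,
            propagation=propagation,
            threshold=_threshold_from_cfg(sub_cfg["threshold"], registry),
            parent=str(sub_cfg.get("parent", "soma")),
        )
    soma_cfg = cfg.get("soma", {})
    soma = HHParams(**{k: float(v) for k, v in soma_cfg.items()})
    return NeuronModel(subunits=subunits, soma=soma, clock=clock)


def save_model(model: NeuronModel, path) -> None:
    cfg = {
        "duration_ms": model.clock.duration,
        "dt_ms": model.clock.dt,
        "subunits": {},
    }
    for bid, sub in model.subunits.items():
        p = sub.threshold
        cfg["subunits"][bid] = {
            "parent": sub.parent,
            "cable": {
                "sections": [
                    {
                        "length": s.length,
                        "diameter": s.diameter,
                        "r_m": s.r_m,
                        "r_a": s.r_a,
                        "c_m": s.c_m,
                    }
                    for s in sub.cable.sections
                ]
            },
            "propagation": {"alpha": sub.propagation.alpha, "beta": sub.propagation.beta},
            "threshold": (
                p.branch_label
                if p.branch_label in load_registry()
                else {
                    "a": p.a, "b": p.b, "c": p.c, "d": p.d,
                    "theta": p.theta, "v_max": p.v_max,
                    "branch_label": p.branch_label,
                }
            ),
        }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def load_protocols(path) -> Dict[str, StimulationProtocol]:
    """Regenerate stimulation protocols from a YAML configuration.

    The file stores the generating configuration (branch, category, synapse
    count, seed, duration, interval, noise), not the sampled placements and
    trains; regeneration from the recorded seed is bit-reproducible.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    protocols = {}
    for entry in cfg["protocols"]:
        proto = make_protocol(
            branch_length=float(entry["branch_length_um"]),
            n_synapses=int(entry["n_synapses"]),
            category=str(entry["category"]),
            seed=int(entry["seed"]),
            branch_id=str(entry["branch_id"]),
            duration_ms=float(entry.get("duration_ms", 1000.0)),
            mean_interval_ms=float(entry.get("mean_interval_ms", 20.0)),
            noise_sd=float(entry.get("noise_sd", 0.2)),
        )
        protocols[proto.branch_id] = proto
    return protocols


def save_protocols(protocols: Dict[str, StimulationProtocol], branch_lengths: Dict[str, float], path) -> None:
    cfg = {
        "protocols": [
            {
                "branch_id": p.branch_id,
                "category": p.category,
                "n_synapses": p.n_synapses,
                "seed": p.seed,
                "branch_length_um": branch_lengths[p.branch_id],
                "duration_ms": p.duration_ms,
                "mean_interval_ms": p.mean_interval_ms,
                "noise_sd": p.noise_sd,
            }
            for p in protocols.values()
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def _digest(path) -> Optional[str]:
    try:
        with open(path, "rb") as fh:
            return hashlib.sha256(fh.read()).hexdigest()
    except OSError:
        return None


def write_manifest(path, command: str, config: dict, seeds: dict, inputs=(), outputs=()) -> None:
    """Write the JSON run manifest for one CLI invocation."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "package_version": __version__,
        "inputs": {str(p): _digest(p) for p in inputs},
        "outputs": {str(p): _digest(p) for p in outputs},
        "wall_clock_start": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def fit_result_to_dict(fit) -> dict:
    p = fit.params
    return {
        "a": p.a, "b": p.b, "c": p.c, "d": p.d,
        "theta": p.theta, "v_max": p.v_max,
        "branch_label": p.branch_label,
        "r_squared_train": fit.r_squared_train,
        "r_squared_test": fit.r_squared_test,
        "split_seed": fit.split_seed,
    }
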