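"""Parameter-recovery harness: the closed loop from simulation through IO
quantification back to the thresholding-function fit.

The harness simulates a branch of the toy neuron under the standard protocol
ensemble (synapse counts 3, 5 and 7), quantifies the thresholding-point
traces into IO records, optionally adds record-level measurement noise to
the observed peaks, fits the subthreshold surface, and reports the recovered
coefficients next to the generating registry row.  A noiseless run isolates
pipeline correctness (recovery is then exact up to floating-point error); a
noisy run measures how much information the record budget actually carries
about each coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import numpy as np
import pandas as pd

from .fitting import fit_threshold_model
from .ioquant import filter_dendritic_spike_artifacts, pair_io, split_regions
from .network import simulate
from .synapse import SYNAPSE_COUNTS, make_protocol
from .toy import make_toy_neuron

__all__ = ["RecoveryReport", "closed_loop_records", "closed_loop_recovery"]


@dataclass
class RecoveryReport:
    """True vs recovered thresholding coefficients and their relative errors."""

    true: Dict[str, float]
    recovered: Dict[str, float]
    relative_errors: Dict[str, float]
    n_records: int
    r_squared_train: float

    @property
    def max_relative_error(self) -> float:
        return max(self.relative_errors.values())


def closed_loop_records(
    branch: str = "primary",
    runs_per_count: int = 3,
    duration_ms: float = 1000.0,
    seed: int = 0,
    category: str = "segregated_whole",
) -> pd.DataFrame:
    """Simulate the toy neuron branch by branch and collect subthreshold IO
    records across synapse counts 3, 5 and 7."""
    model = make_toy_neuron(duration_ms=duration_ms)
    if branch not in model.subunits:
        raise ValueError(f"unknown toy branch {branch!r}")
    sub = model.subunits[branch]
    theta = sub.threshold.theta
    length = sub.cable.length
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.spawn(2 * runs_per_count * len(SYNAPSE_COUNTS))
    frames = []
    k = 0
    for n in SYNAPSE_COUNTS:
        for _ in range(runs_per_count):
            proto_seed = int(run_seeds[k].generate_state(1)[0] % (2**31))
            sim_seed = int(run_seeds[k + 1].generate_state(1)[0] % (2**31))
            k += 2
            proto = make_protocol(
                length, n, category, seed=proto_seed,
                branch_id=branch, duration_ms=duration_ms,
            )
            result = simulate(model, {branch: proto}, seed=sim_seed)
            frames.append(
                pair_io(
                    result.x1_traces[branch],
                    result.f_traces[branch],
                    n,
                    branch=branch,
                )
            )
    records = pd.concat(frames, ignore_index=True)
    filtered = filter_dendritic_spike_artifacts(records, theta)
    subthreshold, _ = split_regions(filtered, theta)
    return subthreshold


def closed_loop_recovery(
    branch: str = "primary",
    n_records: int = 500,
    record_noise_sd: float = 0.01,
    seed: int = 0,
    runs_per_count: int = 3,
    duration_ms: float = 1000.0,
) -> RecoveryReport:
    """Run the full closed loop and fit the thresholding surface.

    ``n_records`` subthreshold records are drawn as a stratified subsample
    (equal shares per synapse count) and ``record_noise_sd`` of Gaussian
    measurement noise is added to the observed peaks before the fit.
    """
    model = make_toy_neuron()
    true_params = model.subunits[branch].threshold
    subthreshold = closed_loop_records(
        branch=branch, runs_per_count=runs_per_count,
        duration_ms=duration_ms, seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    per_count = n_records // len(SYNAPSE_COUNTS)
    shares = [per_count] * len(SYNAPSE_COUNTS)
    shares[0] += n_records - sum(shares)
    parts = []
    for n, share in zip(SYNAPSE_COUNTS, shares):
        group = subthreshold[subthreshold["n_synapses"] == n]
        if len(group) < share:
            raise ValueError(
                f"only {len(group)} subthreshold records at n = {n}; "
                f"increase runs_per_count"
            )
        idx = rng.choice(len(group), size=share, replace=False)
        parts.append(group.iloc[idx])
    sample = pd.concat(parts, ignore_index=True).copy()
    if record_noise_sd > 0:
        sample["v_observed"] = sample["v_observed"] + rng.normal(
            0.0, record_noise_sd, size=len(sample)
        )
    fit = fit_threshold_model(sample, branch_label=branch)
    true = {"a": true_params.a, "b": true_params.b, "c": true_params.c, "d": true_params.d}
    rec = {
        "a": fit.params.a,
        "b": fit.params.b,
        "c": fit.params.c,
        "d": fit.params.d,
    }
    rel = {k: abs((rec[k] - true[k]) / true[k]) for k in true}
    return RecoveryReport(
        true=true,
        recovered=rec,
        relative_errors=rel,
        n_records=len(sample),
        r_squared_train=fit.r_squared_train,
    )
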