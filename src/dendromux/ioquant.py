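"""Input-output quantification of dendritic integration.

The expected signal is the normalized sum of the attenuated, delayed synaptic
inputs at a branch's thresholding point; the observed signal is the measured
(or simulated) potential at the same point.  The observed trace is cut into
time windows bounded by consecutive local minima, each window yields one
(V_expected, V_observed) peak pair, and the resulting records are filtered
for dendritic-spike artifacts and split into sub- and suprathreshold regions
before fitting.

Records are held in a pandas DataFrame with columns ``branch``,
``t_start_ms``, ``t_end_ms``, ``v_expected``, ``v_observed``, ``n_synapses``
(plus ``region`` after splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cable import PropagationParams, propagate
from .core import NormalizationMap, VoltageTrace, require_shared_clock

__all__ = [
    "IODataset",
    "RECORD_COLUMNS",
    "expected_trace",
    "window_by_local_minima",
    "pair_io",
    "filter_dendritic_spike_artifacts",
    "split_regions",
    "bin_means",
]

RECORD_COLUMNS = [
    "branch",
    "t_start_ms",
    "t_end_ms",
    "v_expected",
    "v_observed",
    "n_synapses",
]

# Normalized level above which an observed peak counts as a successful
# (somatic) spike; observed peaks strictly between theta and this level are
# attributed to local dendritic spikes / backpropagation and dropped.
SPIKE_LEVEL = 0.8


@dataclass
class IODataset:
    """Per-window IO records with the threshold used for region splitting."""

    records: pd.DataFrame
    theta: Optional[float] = None

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"records missing columns: {missing}")

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, theta: Optional[float] = None) -> "IODataset":
        return cls(pd.read_csv(path), theta=theta)


def expected_trace(
    spine_traces: Sequence[VoltageTrace],
    site_distances: Sequence[float],
    propagation: PropagationParams,
    nmap: NormalizationMap = NormalizationMap(),
    rest: float = -70.0,
) -> VoltageTrace:
    """Normalized sum of the attenuated inputs at the thresholding point.

    Each spine trace (absolute mV) is converted to electrotonic form
    (``v - rest``), decayed and delayed over its site distance, summed, and
    scaled to normalized units (one normalization span per mV, so rest maps
    to 0).
    """
    if len(spine_traces) != len(site_distances):
        raise ValueError("one distance per spine trace is required")
    if not spine_traces:
        raise ValueError("at least one spine trace is required")
    clock = require_shared_clock(*spine_traces)
    total = np.zeros(clock.n_samples)
    for trace, x in zip(spine_traces, site_distances):
        electro = VoltageTrace(trace.values - rest, clock)
        total += propagate(electro, x, propagation).values
    return VoltageTrace(total / nmap.span, clock)


def window_by_local_minima(trace: VoltageTrace) -> list:
    """Partition a trace into spans bounded by consecutive local minima.

    Interior strict local minima (plateau ties resolved to the first sample
    of the plateau) together with both endpoints bound the windows; returned
    as (start_index, end_index) inclusive pairs whose union covers the trace
    and which overlap only at the shared boundary samples.
    """
    v = trace.values
    if len(v) < 3:
        raise ValueError("windowing needs at least 3 samples")
    minima = []
    i = 1
    n = len(v)
    while i < n - 1:
        if v[i] < v[i - 1]:
            j = i
            while j + 1 < n and v[j + 1] == v[j]:
                j += 1
            if j < n - 1 and v[j + 1] > v[j]:
                minima.append(i)  # first sample of the plateau
            i = j + 1
        else:
            i += 1
    bounds = [0, *minima, n - 1]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


def pair_io(
    expected: VoltageTrace,
    observed: VoltageTrace,
    n_synapses: int,
    windows: Optional[list] = None,
    branch: str = "branch",
) -> pd.DataFrame:
    """One IO record per window: the maximum of each trace inside the span.

    ``windows`` default to :func:`window_by_local_minima` on the observed
    trace, matching how the records are defined.
    """
    clock = require_shared_clock(expected, observed)
    if windows is None:
        windows = window_by_local_minima(observed)
    rows = []
    for i0, i1 in windows:
        sl = slice(i0, i1 + 1)
        rows.append(
            {
                "branch": branch,
                "t_start_ms": i0 * clock.dt,
                "t_end_ms": i1 * clock.dt,
                "v_expected": float(np.max(expected.values[sl])),
                "v_observed": float(np.max(observed.values[sl])),
                "n_synapses": int(n_synapses),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def filter_dendritic_spike_artifacts(
    records: pd.DataFrame, theta: float, spike_level: float = SPIKE_LEVEL
) -> pd.DataFrame:
    """Drop records whose observed peak lies strictly between theta and the
    spike level: those are local dendritic spikes or backpropagation echoes,
    not successful somatic spikes.  Boundary values are kept (open interval).
    """
    if theta >= spike_level:
        raise ValueError("theta must lie below the spike level")
    vo = records["v_observed"]
    keep = ~((vo > theta) & (vo < spike_level))
    return records.loc[keep].reset_index(drop=True)


def split_regions(
    records: pd.DataFrame, theta: float, spike_level: float = SPIKE_LEVEL
) -> tuple:
    """Split filtered records into (subthreshold, suprathreshold) frames.

    Suprathreshold records are successful spikes (observed >= spike level);
    subthreshold records have observed <= theta.  On artifact-filtered input
    the two parts conserve the record count.
    """
    vo = records["v_observed"]
    sub = records.loc[vo <= theta].copy()
    supra = records.loc[vo >= spike_level].copy()
    sub["region"] = "sub"
    supra["region"] = "supra"
    return sub.reset_index(drop=True), supra.reset_index(drop=True)


def bin_means(records: pd.DataFrame, bin_width: float = 0.01) -> pd.DataFrame:
    """Mean observed amplitude per expected-amplitude bin.

    Half-open bins [k*w, (k+1)*w) on ``v_expected``; empty bins are omitted.
    Returns a frame with columns bin_center, mean_v_observed, count.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if records.empty:
        return pd.DataFrame(columns=["bin_center", "mean_v_observed", "count"])
    k = np.floor(records["v_expected"].to_numpy() / bin_width).astype(int)
    df = records.assign(_bin=k)
    grouped = df.groupby("_bin", sort=True)["v_observed"].agg(["mean", "count"])
    return pd.DataFrame(
        {
            "bin_center": (grouped.index.to_numpy() + 0.5) * bin_width,
            "mean_v_observed": grouped["mean"].to_numpy(),
            "count": grouped["count"].to_numpy(),
        }
    )
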