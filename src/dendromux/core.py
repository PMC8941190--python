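"""Shared voltage conventions, the simulation clock, and the trace container.

All membrane potentials are stored internally in millivolts.  The unit-interval
feature scaling used by the IO-quantification and thresholding layers maps the
resting potential (-70 mV by default) to 0 and the somatic action-potential
peak (40 mV) to 1; values outside that band map outside [0, 1] without
clipping, so the map stays bijective and any clipping is an explicit caller
decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationMap",
    "SimulationClock",
    "VoltageTrace",
    "normalize_voltage",
    "denormalize_voltage",
]


@dataclass(frozen=True)
class NormalizationMap:
    """Affine map between membrane potential (mV) and unit-interval features.

    Parameters
    ----------
    v_floor:
        Potential mapped to 0 (mV).  Default -70, the resting potential.
    v_ceiling:
        Potential mapped to 1 (mV).  Default 40, the spike peak.
    """

    v_floor: float = -70.0
    v_ceiling: float = 40.0

    def __post_init__(self) -> None:
        if not self.v_ceiling > self.v_floor:
            raise ValueError(
                f"degenerate normalization map: v_ceiling ({self.v_ceiling}) "
                f"must exceed v_floor ({self.v_floor})"
            )

    @property
    def span(self) -> float:
        """Voltage span in mV mapped onto the unit interval."""
        return self.v_ceiling - self.v_floor

    def normalize(self, v):
        return (np.asarray(v, dtype=float) - self.v_floor) / self.span

    def denormalize(self, u):
        return np.asarray(u, dtype=float) * self.span + self.v_floor


def normalize_voltage(v, nmap: NormalizationMap = NormalizationMap()):
    """Scale membrane potential (mV) onto the unit interval. No clipping."""
    return nmap.normalize(v)


def denormalize_voltage(u, nmap: NormalizationMap = NormalizationMap()):
    """Exact inverse of :func:`normalize_voltage`."""
    return nmap.denormalize(u)


@dataclass(frozen=True)
class SimulationClock:
    """Uniform fixed-step simulation clock.

    ``dt`` defaults to 0.05 ms, the step used throughout the simulator. The
    number of samples is ``floor(duration/dt) + 1`` so both endpoints are
    represented.
    """

    duration: float
    dt: float = 0.05

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def n_samples(self) -> int:
        # tiny epsilon so durations that are exact grid multiples up to
        # floating-point rounding land on the grid point
        return int(np.floor(self.duration / self.dt + 1e-9)) + 1

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential time series.

    ``values`` may be in mV (absolute or electrotonic, i.e. relative to rest)
    or in normalized units; the producing function documents which.
    """

    values: np.ndarray
    clock: SimulationClock

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if len(self.values) != self.clock.n_samples:
            raise ValueError(
                f"trace has {len(self.values)} samples but the clock defines "
                f"{self.clock.n_samples}"
            )

    def times(self) -> np.ndarray:
        return self.clock.times()

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times(), "voltage_mV": self.values})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VoltageTrace":
        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy()
        if len(t) < 2:
            raise ValueError("trace file needs at least two samples")
        dt = float(t[1] - t[0])
        if not np.allclose(np.diff(t), dt, rtol=0, atol=1e-9):
            raise ValueError("trace file is not uniformly sampled")
        clock = SimulationClock(duration=float(t[-1]), dt=dt)
        return cls(df["voltage_mV"].to_numpy(), clock)


def require_shared_clock(*traces: VoltageTrace) -> SimulationClock:
    """Return the common clock of ``traces`` or raise if they disagree."""
    clocks = {(t.clock.dt, t.clock.n_samples) for t in traces}
    if len(clocks) != 1:
        raise ValueError("traces do not share a common clock")
    return traces[0].clock
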