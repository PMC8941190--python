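"""The dynamic piecewise thresholding function and its parameter registry.

A branch's input-output transform on the normalized-voltage scale is

    g(X1, X2) = a + b*X1 + c*X2 + d*X1*X2
    f(X1, X2) = g            if g <= theta (and no forced-spike rule fires)
              = v_max        otherwise

where X1 is the normalized summation of attenuated inputs at the branch's
thresholding point and X2 the number of synapses active on the branch during
the run.  Because the slope in X1 is b + d*X2 with d < 0 for all tabulated
branches, the integration mode shifts from supralinear toward sublinear as
the synapse count grows, and the spiking threshold in X1 moves right — the
threshold is dynamic in X2, not a fixed level.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import yaml

__all__ = [
    "ForcedSpikeRule",
    "ThresholdParams",
    "subthreshold_g",
    "threshold_transform",
    "spiking_threshold_x1",
    "load_registry",
]


@dataclass(frozen=True)
class ForcedSpikeRule:
    """Force the suprathreshold output when x2 > x2_min and x1 > x1_min."""

    x2_min: float
    x1_min: float


@dataclass(frozen=True)
class ThresholdParams:
    """Coefficients of the dynamic thresholding function for one branch.

    ``theta`` may be None for branch classes whose spiking threshold is not
    tabulated; the piecewise transform then refuses to run until a value is
    supplied or estimated.
    """

    a: float
    b: float
    c: float
    d: float
    theta: Optional[float]
    v_max: float
    branch_label: str = ""
    forced_spike_rule: Optional[ForcedSpikeRule] = None
    r_squared: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta is not None:
            if not 0.0 < self.theta < self.v_max:
                raise ValueError("require 0 < theta < v_max")
        if not self.v_max <= 1.0:
            raise ValueError("v_max must not exceed 1 (normalized scale)")

    def with_theta(self, theta: float) -> "ThresholdParams":
        return ThresholdParams(
            a=self.a, b=self.b, c=self.c, d=self.d, theta=theta,
            v_max=self.v_max, branch_label=self.branch_label,
            forced_spike_rule=self.forced_spike_rule, r_squared=self.r_squared,
        )


def subthreshold_g(x1, x2, p: ThresholdParams):
    """Subthreshold integration surface a + b*x1 + c*x2 + d*x1*x2, unclipped."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return p.a + p.b * x1 + p.c * x2 + p.d * x1 * x2


def threshold_transform(x1, x2, p: ThresholdParams):
    """Piecewise output f: the surface g below threshold, v_max above.

    The forced-spike rule, when present, promotes (x1, x2) combinations with
    x2 > x2_min and x1 > x1_min to v_max even where g dips back below theta.
    """
    if p.theta is None:
        raise ValueError(
            f"threshold theta is unset for branch {p.branch_label!r}; "
            "supply one with .with_theta() or estimate it from data"
        )
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    g = subthreshold_g(x1, x2, p)
    spike = g > p.theta
    if p.forced_spike_rule is not None:
        rule = p.forced_spike_rule
        spike = spike | ((x2 > rule.x2_min) & (x1 > rule.x1_min))
    out = np.where(spike, p.v_max, g)
    if out.ndim == 0:
        return float(out)
    return out


def spiking_threshold_x1(x2, p: ThresholdParams):
    """Minimal normalized input summation that spikes at synapse count x2.

    Solves g(x1, x2) = theta for x1 (the forced-spike rule aside).  Requires
    a positive slope b + d*x2; otherwise no finite threshold exists for that
    synapse count.
    """
    if p.theta is None:
        raise ValueError("theta is unset; no spiking threshold is defined")
    x2 = np.asarray(x2, dtype=float)
    slope = p.b + p.d * x2
    if np.any(slope <= 0):
        raise ValueError(
            "b + d*x2 <= 0: no finite spiking threshold exists at this synapse count"
        )
    out = (p.theta - p.a - p.c * x2) / slope
    if out.ndim == 0:
        return float(out)
    return out


def _row_to_params(label: str, row: dict) -> ThresholdParams:
    rule = row.get("forced_spike_rule")
    return ThresholdParams(
        a=float(row["a"]),
        b=float(row["b"]),
        c=float(row["c"]),
        d=float(row["d"]),
        theta=None if row.get("theta") is None else float(row["theta"]),
        v_max=float(row["v_max"]),
        branch_label=label,
        forced_spike_rule=(
            ForcedSpikeRule(x2_min=float(rule["x2_min"]), x1_min=float(rule["x1_min"]))
            if rule
            else None
        ),
        r_squared=None if row.get("r_squared") is None else float(row["r_squared"]),
    )


def load_registry(path=None) -> dict:
    """Load the branch-class parameter registry.

    Without ``path`` the packaged registry is used: primary, secondary and
    tertiary apical rows (with theta and v_max) plus three basal rows whose
    theta is left unset.
    """
    if path is None:
        text = (
            resources.files("dendromux").joinpath("data/threshold_registry.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {label: _row_to_params(label, row) for label, row in raw.items()}
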