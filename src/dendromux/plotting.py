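"""Display helpers: voltage traces and IO curves.

Loess (locally estimated scatterplot) smoothing is available for the
subthreshold IO curve display only; all quantitative outputs elsewhere in the
package use the raw records or plain bin means.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import VoltageTrace
from .ioquant import bin_means

__all__ = ["plot_trace", "plot_io_curve"]


def plot_trace(trace: VoltageTrace, ax=None, **kwargs):
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trace.times(), trace.values, **kwargs)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("membrane potential (mV)")
    return ax


def plot_io_curve(
    records: pd.DataFrame,
    bin_width: float = 0.01,
    smooth: bool = False,
    ax=None,
):
    """Scatter the per-bin mean observed amplitude against expected amplitude,
    optionally with a loess curve through the raw records (display only)."""
    if ax is None:
        _, ax = plt.subplots()
    binned = bin_means(records, bin_width)
    ax.plot(binned["bin_center"], binned["mean_v_observed"], "ko", ms=4)
    if smooth and len(records) >= 10:
        sm = lowess(
            records["v_observed"].to_numpy(),
            records["v_expected"].to_numpy(),
            frac=0.3,
            return_sorted=True,
        )
        ax.plot(sm[:, 0], sm[:, 1], "r-", lw=1)
    lim = max(
        records["v_expected"].max(), records["v_observed"].max(), 1e-3
    )
    ax.plot([0, lim], [0, lim], color="0.7", lw=0.8, zorder=0)
    ax.set_xlabel(r"$V_{expected}$ (normalized)")
    ax.set_ylabel(r"$V_{observed}$ (normalized)")
    return ax
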