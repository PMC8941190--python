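"""Regression estimation of the dynamic thresholding function from IO data.

The subthreshold surface g = a + b*X1 + c*X2 + d*X1*X2 is fitted by ordinary
least squares of the observed peak on {1, v_expected, n, v_expected*n}.  The
spiking threshold theta and the suprathreshold plateau v_max are not
regression outputs: theta is the minimum expected amplitude among successful
spikes (optionally reported per synapse count) and v_max the mean observed
amplitude of the successful spikes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ioquant import IODataset, split_regions
from .threshold import ThresholdParams

__all__ = [
    "FitResult",
    "train_test_split",
    "fit_threshold_model",
    "estimate_theta",
    "estimate_v_max",
    "r_squared",
]


@dataclass
class FitResult:
    """Fitted thresholding-function parameters and goodness of fit."""

    params: ThresholdParams
    r_squared_train: float
    r_squared_test: Optional[float]
    split_seed: Optional[int] = None
    std_errors: Optional[dict] = None


def train_test_split(
    records: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple:
    """Disjoint random partition of records, reproducible per seed.

    The training size is ``round(train_fraction * N)`` so a 10-record set at
    the default fraction splits 7 / 3.
    """
    if records.empty:
        raise ValueError("cannot split an empty dataset")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = len(records)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    train = records.iloc[perm[:n_train]].reset_index(drop=True)
    test = records.iloc[perm[n_train:]].reset_index(drop=True)
    return train, test


def _design(records: pd.DataFrame) -> np.ndarray:
    x1 = records["v_expected"].to_numpy(dtype=float)
    x2 = records["n_synapses"].to_numpy(dtype=float)
    return np.column_stack([np.ones_like(x1), x1, x2, x1 * x2])


def fit_threshold_model(
    train: pd.DataFrame,
    test: Optional[pd.DataFrame] = None,
    theta: Optional[float] = None,
    v_max: Optional[float] = None,
    branch_label: str = "",
    split_seed: Optional[int] = None,
) -> FitResult:
    """OLS fit of the subthreshold surface on training records.

    Requires at least five records spanning at least two distinct synapse
    counts; a single count makes the c and d coefficients unidentifiable and
    raises.  ``theta``/``v_max`` are attached to the result if supplied (for
    example from :func:`estimate_theta` / :func:`estimate_v_max`).
    """
    if len(train) < 5:
        raise ValueError("need at least 5 training records")
    counts = train["n_synapses"].nunique()
    if counts < 2:
        raise ValueError(
            "rank-deficient design: records span a single synapse count, "
            "c and d are unidentifiable"
        )
    X = _design(train)
    y = train["v_observed"].to_numpy(dtype=float)
    model = sm.OLS(y, X).fit()
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("rank-deficient design matrix")
    a, b, c, d = model.params
    params = ThresholdParams(
        a=float(a), b=float(b), c=float(c), d=float(d),
        theta=theta, v_max=1.0 if v_max is None else float(v_max),
        branch_label=branch_label,
    )
    r2_test = None
    if test is not None and len(test) >= 2:
        pred = _design(test) @ model.params
        r2_test = r_squared(test["v_observed"].to_numpy(dtype=float), pred)
    return FitResult(
        params=params,
        r_squared_train=float(model.rsquared),
        r_squared_test=r2_test,
        split_seed=split_seed,
        std_errors=dict(zip("abcd", (float(se) for se in model.bse))),
    )


def estimate_theta(dataset: IODataset, per_n: bool = False):
    """Spiking threshold: minimum expected amplitude among successful spikes.

    With ``per_n`` the per-synapse-count minima are returned as a Series
    (the per-count threshold lines), otherwise the overall minimum.
    """
    if dataset.theta is None:
        raise ValueError("dataset.theta (region-splitting level) is required")
    _, supra = split_regions(dataset.records, dataset.theta)
    if supra.empty:
        raise ValueError("no suprathreshold records to estimate theta from")
    if per_n:
        return supra.groupby("n_synapses")["v_expected"].min()
    return float(supra["v_expected"].min())


def estimate_v_max(dataset: IODataset) -> float:
    """Suprathreshold plateau: mean observed amplitude of successful spikes."""
    if dataset.theta is None:
        raise ValueError("dataset.theta (region-splitting level) is required")
    _, supra = split_regions(dataset.records, dataset.theta)
    if supra.empty:
        raise ValueError("no suprathreshold records to estimate v_max from")
    return float(supra["v_observed"].mean())


def r_squared(actual, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    actual = np.asarray(actual, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if actual.shape != predicted.shape or actual.size < 2:
        raise ValueError("need equal-length arrays with at least 2 values")
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("actual values have zero variance")
    ss_res = float(np.sum((actual - predicted) ** 2))
    return 1.0 - ss_res / ss_tot
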