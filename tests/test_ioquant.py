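"""IO quantification: windowing, pairing, artifact filtering, regions, bins."""

import numpy as np
import pandas as pd
import pytest

from dendromux.cable import PropagationParams
from dendromux.core import NormalizationMap, SimulationClock, VoltageTrace
from dendromux.ioquant import (
    bin_means,
    expected_trace,
    filter_dendritic_spike_artifacts,
    pair_io,
    split_regions,
    window_by_local_minima,
)


def _trace(values, dt=1.0):
    values = np.asarray(values, dtype=float)
    clock = SimulationClock(duration=(len(values) - 1) * dt, dt=dt)
    return VoltageTrace(values, clock)


def brute_force_windows(values):
    """Independent oracle: scan every interior sample for strict local
    minimality (plateaus resolved to their first sample)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    minima = []
    for i in range(1, n - 1):
        j = i
        while j + 1 < n and values[j + 1] == values[j]:
            j += 1
        if j == n - 1:
            continue
        if values[i] < values[i - 1] and values[j + 1] > values[j]:
            minima.append(i)
    bounds = [0, *minima, n - 1]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]


class TestWindowing:
    def test_constructed_example(self):
        windows = window_by_local_minima(_trace([0, 0.5, 0.2, 0.8, 0.1, 0.6, 0]))
        assert windows == [(0, 2), (2, 4), (4, 6)]

    def test_monotone_trace_single_window(self):
        assert window_by_local_minima(_trace([0, 1, 2, 3])) == [(0, 3)]
        assert window_by_local_minima(_trace([3, 2, 1, 0])) == [(0, 3)]

    def test_plateau_minimum_resolves_to_first_sample(self):
        windows = window_by_local_minima(_trace([5, 1, 1, 1, 4, 2, 6]))
        assert (0, 1) in windows and (1, 5) in windows

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            window_by_local_minima(_trace([0, 1]))

    def test_partition_property_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 400)
            values = np.round(rng.standard_normal(n), 2)  # duplicates induce plateaus
            windows = window_by_local_minima(_trace(values))
            assert windows == brute_force_windows(values)
            assert windows[0][0] == 0
            assert windows[-1][1] == n - 1
            for (a0, a1), (b0, b1) in zip(windows, windows[1:]):
                assert a1 == b0
                assert a0 < a1


class TestPairing:
    def test_identical_traces_pair_identically(self):
        obs = _trace([0, 0.5, 0.2, 0.8, 0.1, 0.6, 0])
        records = pair_io(obs, obs, n_synapses=3)
        assert np.allclose(records["v_expected"], records["v_observed"])

    def test_constant_expected_toy_example(self):
        obs = _trace([0, 0.5, 0.2, 0.8, 0.1, 0.6, 0])
        exp = _trace(np.full(7, 0.1))
        records = pair_io(exp, obs, n_synapses=3)
        assert list(records["v_observed"]) == [0.5, 0.8, 0.6]
        assert np.allclose(records["v_expected"], 0.1)
        assert len(records) == len(window_by_local_minima(obs))

    def test_brute_force_equivalence_on_random_traces(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 1000))
            obs = _trace(rng.standard_normal(n))
            exp = _trace(rng.standard_normal(n))
            records = pair_io(exp, obs, n_synapses=5)
            for row, (i0, i1) in zip(
                records.itertuples(), window_by_local_minima(obs)
            ):
                assert row.v_observed == obs.values[i0 : i1 + 1].max()
                assert row.v_expected == exp.values[i0 : i1 + 1].max()

    def test_clock_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pair_io(_trace([0, 1, 0]), _trace([0, 1, 0, 1]), n_synapses=1)


class TestExpectedTrace:
    clock = SimulationClock(20.0, dt=0.05)

    def _spike(self, t0):
        t = self.clock.times()
        return VoltageTrace(-70 + 10 * np.exp(-((t - t0) ** 2) / 1.0), self.clock)

    def test_zero_distance_unit_alpha_is_identity(self):
        params = PropagationParams(alpha=1.0, beta=0.0, lambda_total=500.0, tau_total=10.0)
        spine = self._spike(8.0)
        out = expected_trace([spine], [0.0], params)
        expected = (spine.values + 70.0) / NormalizationMap().span
        assert np.allclose(out.values, expected)

    def test_two_identical_inputs_double_the_sum(self):
        params = PropagationParams(alpha=0.8, beta=0.1, lambda_total=500.0, tau_total=10.0)
        spine = self._spike(8.0)
        one = expected_trace([spine], [100.0], params)
        two = expected_trace([spine, spine], [100.0, 100.0], params)
        assert np.allclose(two.values, 2 * one.values)

    def test_distal_input_delays_the_summed_peak(self):
        # 300 um at this beta delays the distal copy by ~0.5 ms, so the
        # summed waveform peaks later than the near input alone
        params = PropagationParams(alpha=1.0, beta=0.001, lambda_total=500.0, tau_total=10.0)
        near = expected_trace([self._spike(8.0)], [1.0], params)
        both = expected_trace(
            [self._spike(8.0), self._spike(8.0)], [1.0, 300.0], params
        )
        assert np.argmax(both.values) > np.argmax(near.values)


class TestArtifactFilter:
    def _records(self, observed):
        return pd.DataFrame(
            {
                "branch": "b",
                "t_start_ms": 0.0,
                "t_end_ms": 1.0,
                "v_expected": 0.05,
                "v_observed": observed,
                "n_synapses": 3,
            }
        )

    def test_open_interval_rule(self):
        records = self._records([0.10, 0.30, 0.85, 0.975])
        kept = filter_dendritic_spike_artifacts(records, theta=0.15)
        assert list(kept["v_observed"]) == [0.10, 0.85, 0.975]

    def test_boundaries_kept(self):
        records = self._records([0.15, 0.8])
        kept = filter_dendritic_spike_artifacts(records, theta=0.15)
        assert len(kept) == 2

    def test_empty_input(self):
        records = self._records([])
        assert filter_dendritic_spike_artifacts(records, theta=0.15).empty

    def test_idempotent(self):
        records = self._records(np.linspace(0, 1, 50))
        once = filter_dendritic_spike_artifacts(records, theta=0.2)
        twice = filter_dendritic_spike_artifacts(once, theta=0.2)
        pd.testing.assert_frame_equal(once, twice)

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            filter_dendritic_spike_artifacts(self._records([0.1]), theta=0.85)


class TestRegionsAndBins:
    def _records(self, observed, expected=None):
        observed = np.asarray(observed, dtype=float)
        return pd.DataFrame(
            {
                "branch": "b",
                "t_start_ms": 0.0,
                "t_end_ms": 1.0,
                "v_expected": expected if expected is not None else observed,
                "v_observed": observed,
                "n_synapses": 3,
            }
        )

    def test_all_subthreshold(self):
        sub, supra = split_regions(self._records([0.01, 0.05]), theta=0.15)
        assert len(sub) == 2 and supra.empty

    def test_counts_conserved_after_filter(self):
        records = self._records([0.10, 0.30, 0.85, 0.975])
        filtered = filter_dendritic_spike_artifacts(records, theta=0.15)
        sub, supra = split_regions(filtered, theta=0.15)
        assert len(sub) + len(supra) == len(filtered)
        assert list(sub["v_observed"]) == [0.10]
        assert sorted(supra["v_observed"]) == [0.85, 0.975]

    def test_bin_means_against_brute_force(self):
        records = self._records([0.4, 0.6, 0.9], expected=[0.01, 0.012, 0.03])
        out = bin_means(records, bin_width=0.02)
        assert len(out) == 2
        assert out["mean_v_observed"].iloc[0] == pytest.approx(np.mean([0.4, 0.6]))
        assert out["mean_v_observed"].iloc[1] == pytest.approx(0.9)
        assert out["count"].sum() == 3

    def test_single_record_single_bin(self):
        out = bin_means(self._records([0.3], expected=[0.123]), bin_width=0.05)
        assert len(out) == 1
        assert out["count"].iloc[0] == 1

    def test_bin_count_conservation_random(self):
        rng = np.random.default_rng(3)
        records = self._records(rng.uniform(0, 1, 500), expected=rng.uniform(0, 1, 500))
        out = bin_means(records, bin_width=0.01)
        assert out["count"].sum() == 500

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            bin_means(self._records([0.1]), bin_width=0.0)
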