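"""Synaptic conductances, Poisson trains, EPSP traces and protocols."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from dendromux.core import SimulationClock
from dendromux.synapse import (
    AMPAKinetics,
    EPSPShape,
    NMDAKinetics,
    PLACEMENT_WINDOWS,
    SpikeTrain,
    ampa_conductance,
    enumerate_input_categories,
    epsp_time_constants,
    generate_spike_train,
    make_protocol,
    mg_block,
    nmda_conductance,
    run_allocation,
    spine_epsp_trace,
)


class TestConductances:
    def test_causality_before_onset(self):
        t = np.linspace(0, 9.99, 1000)
        assert np.all(ampa_conductance(t, onset=10.0) == 0.0)
        assert np.all(nmda_conductance(t, onset=10.0, v=-70.0) == 0.0)

    def test_ampa_peak_normalization(self):
        kin = AMPAKinetics()
        t = np.arange(0, 50, 1e-4)
        g = ampa_conductance(t, onset=0.0, kin=kin)
        assert abs(g.max() - kin.g_max) < 1e-9

    def test_ampa_time_to_peak_closed_form(self):
        kin = AMPAKinetics()
        t = np.arange(0, 10, 1e-5)
        g = ampa_conductance(t, onset=0.0, kin=kin)
        t_peak = t[np.argmax(g)]
        expected = (kin.tau_rise * kin.tau_decay / (kin.tau_decay - kin.tau_rise)) * math.log(
            kin.tau_decay / kin.tau_rise
        )
        assert t_peak == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.5117, abs=1e-4)

    def test_mg_block_values(self):
        assert mg_block(0.0, 1.0) == pytest.approx(3.57 / 4.57, rel=1e-12)
        assert mg_block(500.0, 1.0) == pytest.approx(1.0, abs=1e-12)
        v = np.linspace(-120, 100, 500)
        b = mg_block(v)
        assert np.all((b > 0) & (b <= 1))

    def test_nmda_peak_normalization_without_block(self):
        kin = NMDAKinetics(mg_out=0.0)
        t = np.arange(0, 600, 1e-3)
        g = nmda_conductance(t, onset=0.0, v=-70.0, kin=kin)
        assert abs(g.max() - kin.g_max) < 1e-9

    def test_waveforms_nonnegative_and_decaying(self):
        t = np.arange(0, 400, 0.05)
        g = ampa_conductance(t, onset=5.0)
        assert np.all(g >= 0)
        assert g[-1] < 1e-9

    def test_degenerate_kinetics_rejected(self):
        with pytest.raises(ValueError):
            AMPAKinetics(tau_rise=2.0, tau_decay=2.0)
        with pytest.raises(ValueError):
            NMDAKinetics(tau_rise=5.0, tau_decay=2.0)


class TestSpikeTrain:
    def test_determinism(self):
        a = generate_spike_train(20.0, 1000.0, seed=7)
        b = generate_spike_train(20.0, 1000.0, seed=7)
        assert a.activation_times == b.activation_times

    def test_mean_count_matches_poisson_rate(self):
        # Monte-Carlo oracle: expected count = duration/mean = 50
        counts = [
            len(generate_spike_train(20.0, 1000.0, seed=s).activation_times)
            for s in range(1000)
        ]
        mean = np.mean(counts)
        sem = np.std(counts) / math.sqrt(len(counts))
        assert abs(mean - 50.0) < 3 * sem + 1e-9

    def test_empty_probability_for_long_interval(self):
        # P(no activation) = exp(-duration/mean) ~ 1 - duration/mean for mean >> duration
        mean_interval, duration = 10_000.0, 100.0
        empties = sum(
            1
            for s in range(2000)
            if not generate_spike_train(mean_interval, duration, seed=s).activation_times
        )
        expected = math.exp(-duration / mean_interval)
        assert empties / 2000 == pytest.approx(expected, abs=0.025)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_spike_train(0.0, 100.0, seed=0)
        with pytest.raises(ValueError):
            generate_spike_train(20.0, -1.0, seed=0)
        with pytest.raises(ValueError):
            SpikeTrain((5.0, 5.0))


class TestEPSPTrace:
    def test_empty_train_rests(self):
        clock = SimulationClock(100.0)
        trace = spine_epsp_trace(SpikeTrain(()), EPSPShape(), 0.0, clock, 0)
        assert np.all(trace.values == -70.0)

    def test_single_event_peak_amplitude(self):
        clock = SimulationClock(100.0)
        trace = spine_epsp_trace(SpikeTrain((20.0,)), EPSPShape(), 0.0, clock, 0)
        assert trace.values.max() == pytest.approx(-55.19, abs=0.01)

    def test_calibrated_peak_and_fwhm(self):
        shape = EPSPShape()
        clock = SimulationClock(200.0, dt=0.001)
        trace = spine_epsp_trace(SpikeTrain((10.0,)), shape, 0.0, clock, 0)
        depol = trace.values - shape.rest
        peak = depol.max()
        assert peak == pytest.approx(shape.peak_amplitude, rel=0.005)
        above = np.flatnonzero(depol >= peak / 2.0)
        fwhm = (above[-1] - above[0]) * clock.dt
        assert fwhm == pytest.approx(shape.half_width, rel=0.005)

    def test_linear_superposition_of_well_separated_events(self):
        clock = SimulationClock(200.0)
        trace = spine_epsp_trace(SpikeTrain((30.0, 130.0)), EPSPShape(), 0.0, clock, 0)
        t = clock.times()
        peak1 = trace.values[(t >= 30) & (t < 100)].max()
        peak2 = trace.values[(t >= 130)].max()
        assert peak1 == pytest.approx(peak2, abs=1e-6)

    def test_noise_seed_reproducibility(self):
        clock = SimulationClock(50.0)
        a = spine_epsp_trace(SpikeTrain((10.0,)), EPSPShape(), 0.5, clock, 3)
        b = spine_epsp_trace(SpikeTrain((10.0,)), EPSPShape(), 0.5, clock, 3)
        assert np.array_equal(a.values, b.values)

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            EPSPShape(half_width=-1.0)
        with pytest.raises(ValueError):
            EPSPShape(peak_amplitude=0.0)

    def test_time_constants_scale_with_half_width(self):
        tr1 = epsp_time_constants(EPSPShape(half_width=2.75))
        tr2 = epsp_time_constants(EPSPShape(half_width=5.5))
        assert tr2[0] == pytest.approx(2 * tr1[0])
        assert tr2[1] == pytest.approx(2 * tr1[1])


class TestProtocols:
    def test_category_enumeration(self):
        cats = enumerate_input_categories()
        assert len(cats) == 21
        assert len({c for c, _ in cats}) == 7
        assert sorted({n for _, n in cats}) == [3, 5, 7]

    def test_run_allocation_per_branch(self):
        alloc = run_allocation()
        assert alloc["segregated_whole"] == 10
        assert sum(alloc.values()) == 40

    def test_run_allocation_per_count(self):
        alloc = run_allocation("per_count")
        assert sum(alloc.values()) == 120
        assert alloc[("segregated_whole", 5)] == 10

    def test_window_containment(self):
        proto = make_protocol(100.0, 7, "clustered_q4", seed=1)
        for site in proto.sites:
            assert 0.75 <= site.fraction <= 1.0
            assert site.position == pytest.approx(site.fraction * 100.0)

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError):
            make_protocol(100.0, 3, "scattered", seed=0)

    def test_protocol_reproducibility(self):
        a = make_protocol(80.0, 5, "segregated_whole", seed=11)
        b = make_protocol(80.0, 5, "segregated_whole", seed=11)
        assert [s.fraction for s in a.sites] == [s.fraction for s in b.sites]
        assert all(
            x.activation_times == y.activation_times for x, y in zip(a.trains, b.trains)
        )

    @pytest.mark.parametrize("category", sorted(PLACEMENT_WINDOWS))
    def test_placement_uniform_within_window(self, category):
        lo, hi = PLACEMENT_WINDOWS[category]
        fractions = np.concatenate(
            [
                [s.fraction for s in make_protocol(1.0, 5, category, seed=s).sites]
                for s in range(200)
            ]
        )
        stat = kstest(fractions, "uniform", args=(lo, hi - lo))
        assert stat.pvalue > 1e-4
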