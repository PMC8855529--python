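"""Tests of the synchronization measures: LFP proxies, band-pass + Hilbert
phase extraction, mean phase coherence, Kuramoto order parameter, dominant
frequencies, ISI statistics, and cycle participation."""

import numpy as np
import pytest

from gammasync.sim_engine import SpikeRecord
from gammasync.sync_measures import (
    NetworkSignal,
    PhaseSeries,
    bandpass,
    cycle_participation,
    cycle_windows,
    dominant_frequency,
    frequency_ratio,
    instantaneous_phase,
    isi_statistics,
    kuramoto_order,
    lfp_current_proxy,
    lfp_voltage_proxy,
    mean_phase_coherence,
    measure_run,
)

FS = 2000.0


def tone(freq, duration_s=3.0, fs=FS, phase=0.0, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.cos(2 * np.pi * freq * t + phase)


class TestLfpProxies:
    def test_single_trace_passthrough(self):
        x = tone(60.0)
        sig = lfp_voltage_proxy(x, FS)
        assert np.allclose(sig.samples, x)

    def test_linearity_cancellation(self):
        x = tone(60.0)
        sig = lfp_voltage_proxy(np.vstack([x, -x]), FS)
        assert np.allclose(sig.samples, 0.0)

    def test_identical_traces_average_to_themselves(self):
        x = tone(45.0)
        sig = lfp_voltage_proxy(np.tile(x, (7, 1)), FS)
        assert np.allclose(sig.samples, x)

    def test_current_proxy_is_sign_invariant(self):
        iA = tone(60.0, amp=3.0)
        iG = tone(60.0, amp=2.0, phase=1.0)
        a = lfp_current_proxy(iA, iG, FS)
        b = lfp_current_proxy(-iA, -iG, FS)
        assert np.allclose(a.samples, b.samples)
        assert np.all(a.samples >= 0)

    def test_zero_currents_zero_signal(self):
        sig = lfp_current_proxy(np.zeros((3, 100)), np.zeros((3, 100)), FS)
        assert np.all(sig.samples == 0.0)


class TestBandpass:
    def test_passband_tone_preserved_zero_phase(self):
        x = NetworkSignal(tone(60.0), FS)
        y = bandpass(x)
        core = slice(1000, -1000)
        amp = np.max(np.abs(y.samples[core]))
        assert abs(amp - 1.0) < 0.05
        # zero-phase: filtered output stays aligned with the input
        lag = np.argmax(np.correlate(y.samples[core], x.samples[core],
                                     "full")) - (y.samples[core].size - 1)
        assert lag == 0

    def test_out_of_band_tone_attenuated(self):
        y = bandpass(NetworkSignal(tone(5.0), FS))
        assert np.max(np.abs(y.samples[1000:-1000])) < 0.1

    def test_zero_in_zero_out(self):
        y = bandpass(NetworkSignal(np.zeros(4000), FS))
        assert np.allclose(y.samples, 0.0)

    def test_undersampled_signal_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            bandpass(NetworkSignal(np.zeros(100), 200.0))


class TestInstantaneousPhase:
    def test_phase_advances_at_tone_frequency(self):
        ph = instantaneous_phase(NetworkSignal(tone(60.0), FS))
        rate = np.diff(np.unwrap(ph.phase)).mean() * FS / (2 * np.pi)
        assert rate == pytest.approx(60.0, rel=1e-3)

    def test_quarter_cycle_offset_between_cos_and_sin(self):
        a = instantaneous_phase(NetworkSignal(tone(60.0), FS))
        b = instantaneous_phase(
            NetworkSignal(tone(60.0, phase=-np.pi / 2), FS))
        d = np.angle(np.exp(1j * (a.phase - b.phase)))
        assert np.allclose(d, np.pi / 2, atol=1e-3)

    def test_amplitude_invariance(self):
        a = instantaneous_phase(NetworkSignal(tone(60.0), FS))
        b = instantaneous_phase(NetworkSignal(tone(60.0, amp=7.3), FS))
        assert np.allclose(a.phase, b.phase, atol=1e-9)

    def test_edge_trim_applied(self):
        sig = NetworkSignal(tone(60.0), FS)
        ph = instantaneous_phase(sig)
        assert ph.phase.shape[0] == sig.samples.shape[0] - 2 * int(0.1 * FS)


class TestMeanPhaseCoherence:
    def test_identical_phases(self):
        p = PhaseSeries(np.linspace(0, 100, 5000) % (2 * np.pi), FS)
        assert mean_phase_coherence(p, p) == pytest.approx(1.0)

    def test_constant_lag_is_full_coherence(self):
        base = np.linspace(0, 200, 5000) % (2 * np.pi)
        a = PhaseSeries(base, FS)
        b = PhaseSeries(base + 0.7, FS)
        assert mean_phase_coherence(a, b) == pytest.approx(1.0)

    def test_uniformly_drifting_difference_vanishes(self):
        # Phase differences hitting the T-th roots of unity sum to zero.
        T = 1000
        diff = 2 * np.pi * np.arange(T) / T
        a = PhaseSeries(diff, FS)
        b = PhaseSeries(np.zeros(T), FS)
        assert mean_phase_coherence(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(0)
        a = PhaseSeries(rng.uniform(-np.pi, np.pi, 200), FS)
        b = PhaseSeries(rng.uniform(-np.pi, np.pi, 200), FS)
        brute = abs(sum(np.exp(1j * (x - y))
                        for x, y in zip(a.phase, b.phase)) / 200)
        assert mean_phase_coherence(a, b) == pytest.approx(brute, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_phase_coherence(PhaseSeries(np.zeros(10), FS),
                                 PhaseSeries(np.zeros(11), FS))

    def test_bounded_and_offset_invariant_on_random_input(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            a = PhaseSeries(rng.uniform(-np.pi, np.pi, 500), FS)
            b = PhaseSeries(rng.uniform(-np.pi, np.pi, 500), FS)
            r = mean_phase_coherence(a, b)
            assert 0.0 <= r <= 1.0
            shifted = PhaseSeries(a.phase + 1.234, FS)
            assert mean_phase_coherence(shifted, b) == pytest.approx(r)


class TestKuramotoOrder:
    def test_identical_population(self):
        base = np.linspace(0, 300, 4000)
        phases = np.tile(base, (10, 1))
        assert kuramoto_order(phases) == pytest.approx(1.0)

    def test_antiphase_pair(self):
        base = np.linspace(0, 300, 4000)
        phases = np.vstack([base, base + np.pi])
        assert kuramoto_order(phases) == pytest.approx(0.0, abs=1e-12)

    def test_evenly_dispersed_population(self):
        base = np.linspace(0, 300, 4000)
        offsets = 2 * np.pi * np.arange(8) / 8
        phases = base[None, :] + offsets[:, None]
        assert kuramoto_order(phases) == pytest.approx(0.0, abs=1e-10)

    def test_sensitive_to_constant_lags_unlike_R(self):
        # The reason two measures exist: K penalizes nonzero lags among
        # neurons while R forgives a constant lag between networks.
        base = np.linspace(0, 300, 4000)
        lagged = np.vstack([base, base + 2.0])
        assert kuramoto_order(lagged) < 0.6
        assert mean_phase_coherence(
            PhaseSeries(base, FS), PhaseSeries(base + 2.0, FS)) == \
            pytest.approx(1.0)

    def test_bounds_on_random_phases(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-np.pi, np.pi, size=(20, 500))
        assert 0.0 <= kuramoto_order(phases) <= 1.0


class TestDominantFrequency:
    def test_pure_tone(self):
        assert dominant_frequency(NetworkSignal(tone(60.0, 5.0), FS)) == \
            pytest.approx(60.0, abs=1.0)

    def test_strongest_component_wins(self):
        x = tone(40.0, 5.0) + 0.1 * tone(80.0, 5.0)
        assert dominant_frequency(NetworkSignal(x, FS)) == \
            pytest.approx(40.0, abs=1.0)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError):
            dominant_frequency(NetworkSignal(np.ones(4000), FS))

    def test_welch_resolution_is_1hz_on_long_signals(self):
        x = NetworkSignal(tone(55.0, 5.0), FS)
        assert dominant_frequency(x) == pytest.approx(55.0, abs=1.0)


class TestFrequencyRatio:
    def test_locked(self):
        assert frequency_ratio(60.0, 60.0) == 1.0

    def test_reported_state1_pair(self):
        assert frequency_ratio(55.0, 39.0) == pytest.approx(0.709, abs=1e-3)

    def test_order_invariance(self):
        assert frequency_ratio(39.0, 55.0) == frequency_ratio(55.0, 39.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            frequency_ratio(0.0, 50.0)


class TestIsiStatistics:
    def test_single_periodic_neuron(self):
        times = np.arange(20.0, 1000.0, 20.0)
        rec = SpikeRecord(np.zeros(times.size, dtype=int), times, 1, 1000.0)
        st = isi_statistics(rec)
        assert st.mean == pytest.approx(20.0)
        assert st.var == pytest.approx(0.0)
        assert st.hist[20] == st.n_intervals

    def test_pooling_across_neurons(self):
        ids = np.array([0, 0, 0, 1, 1, 1])
        times = np.array([0.0, 10.0, 20.0, 0.0, 30.0, 60.0])
        order = np.argsort(times, kind="stable")
        rec = SpikeRecord(ids[order], times[order], 2, 100.0)
        st = isi_statistics(rec)
        assert st.n_intervals == 4
        assert st.mean == pytest.approx(20.0)

    def test_empty_record_flagged(self):
        rec = SpikeRecord(np.empty(0, dtype=int), np.empty(0), 5, 100.0)
        st = isi_statistics(rec)
        assert st.empty
        assert np.isnan(st.mean)


class TestCycleParticipation:
    def test_full_participation_on_synthetic_rhythm(self):
        ref = NetworkSignal(tone(50.0, 2.0), FS)
        windows = cycle_windows(ref)
        n_neurons = 20
        # every neuron spikes at every oscillation peak
        peak_times = np.arange(0.0, 2000.0, 20.0) + 0.01
        ids = np.repeat(np.arange(n_neurons), peak_times.size)
        times = np.tile(peak_times, n_neurons)
        order = np.argsort(times, kind="stable")
        rec = SpikeRecord(ids[order], times[order], n_neurons, 2000.0)
        fractions, matrix = cycle_participation(rec, windows)
        assert np.all(fractions > 0.99)
        assert matrix.shape == (n_neurons, windows.shape[0])

    def test_silent_population_participates_nowhere(self):
        ref = NetworkSignal(tone(50.0, 2.0), FS)
        windows = cycle_windows(ref)
        rec = SpikeRecord(np.empty(0, dtype=int), np.empty(0), 10, 2000.0)
        fractions, _ = cycle_participation(rec, windows)
        assert np.all(fractions == 0.0)

    def test_no_cycles_rejected(self):
        rec = SpikeRecord(np.empty(0, dtype=int), np.empty(0), 10, 100.0)
        with pytest.raises(ValueError):
            cycle_participation(rec, np.empty((0, 2)))

    def test_cycle_skipping_visible_in_matrix(self):
        ref = NetworkSignal(tone(50.0, 2.0), FS)
        windows = cycle_windows(ref)
        # one neuron fires only on every other cycle
        times = np.arange(0.0, 2000.0, 40.0) + 0.01
        rec = SpikeRecord(np.zeros(times.size, dtype=int), times, 1, 2000.0)
        _, matrix = cycle_participation(rec, windows)
        hits = matrix[0].astype(int)
        assert 0.3 < hits.mean() < 0.7
        # a skipped cycle is followed by a participating one
        assert np.all(hits[:-1] + hits[1:] >= 1)


class TestMeasurePipeline:
    def test_full_pipeline_on_simulation(self, small_ei_result):
        m = measure_run(small_ei_result)
        assert 0.0 <= m.R <= 1.0
        assert all(0.0 <= k <= 1.0 for k in m.K.values())
        assert m.f1 >= m.f2 > 0
        assert 0.0 < m.r <= 1.0
        assert set(m.isi) == {"E1", "I1", "E2", "I2"}

    def test_current_proxy_preserves_rhythm_frequency(self):
        # Synaptic currents keep one sign (conductances are non-negative and
        # the driving force rarely reverses), so the absolute value in the
        # current proxy does not double the rhythm frequency.
        t = np.arange(int(3.0 * FS)) / FS
        iA = 50.0 + 20.0 * np.cos(2 * np.pi * 60.0 * t)
        iG = 80.0 + 30.0 * np.cos(2 * np.pi * 60.0 * t + 1.0)
        sig = lfp_current_proxy(iA, iG, FS)
        assert dominant_frequency(bandpass(sig)) == pytest.approx(60.0,
                                                                  abs=1.0)

    def test_current_proxy_runs_through_pipeline(self, small_ei_result):
        mc = measure_run(small_ei_result, proxy="current")
        assert 0.0 <= mc.R <= 1.0
        assert mc.f1 >= mc.f2 > 0
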