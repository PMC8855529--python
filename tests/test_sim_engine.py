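"""Tests of the two-network simulation engine."""

import json
from dataclasses import replace

import numpy as np
import pytest

from gammasync.model_core import INHIBITORY_ADEX
from gammasync.network_build import PopulationSpec, ScenarioSpec, build_scenario
from gammasync.model_core import CouplingStrengths, SynapseParams
from gammasync.noise_drive import NoiseParams
from gammasync.sim_engine import (
    SimulationConfig,
    load_result_traces,
    run,
    save_result,
)


def quiet_two_pop_spec(n=30, **noise_kw):
    """Two uncoupled inhibitory populations that receive no noise."""
    pops = (
        PopulationSpec("I1", n, INHIBITORY_ADEX, 1, "I", 0.0),
        PopulationSpec("I2", n, INHIBITORY_ADEX, 2, "I", 0.0),
    )
    return ScenarioSpec(scenario=1, populations=pops, projections=(),
                        synapse=SynapseParams(),
                        noise=NoiseParams(**noise_kw),
                        coupling=CouplingStrengths(), duration=300.0,
                        dt=0.5, seed=0)


class TestRestingDynamics:
    def test_no_input_no_spikes_and_relaxation_to_rest(self):
        # Without noise or coupling the subthreshold state relaxes toward
        # the resting equilibrium near E_L and never spikes.
        spec = quiet_two_pop_spec()
        res = run(spec, SimulationConfig(dt=0.5, duration=400.0,
                                         transient_discard=0.0, seed=1))
        assert all(rec.n_spikes == 0 for rec in res.spikes.values())
        final = res.traces["I1"].V[:, -1]
        assert np.all(np.abs(final - INHIBITORY_ADEX.E_L) < 1.0)

    def test_zero_duration_gives_empty_records(self):
        spec = quiet_two_pop_spec()
        res = run(spec, SimulationConfig(dt=0.5, duration=0.0,
                                         transient_discard=0.0, seed=1))
        assert all(rec.n_spikes == 0 for rec in res.spikes.values())
        assert res.time.size == 0


class TestDeterminism:
    def test_same_seed_identical_rasters(self):
        spec = build_scenario(3, N_E=50, N_I=14, seed=21)
        cfg = SimulationConfig(dt=0.25, duration=600.0,
                               transient_discard=100.0, seed=21)
        a, b = run(spec, cfg), run(spec, cfg)
        for pid in a.spikes:
            assert np.array_equal(a.spikes[pid].neuron_ids,
                                  b.spikes[pid].neuron_ids)
            assert np.array_equal(a.spikes[pid].times, b.spikes[pid].times)

    def test_different_seeds_differ(self):
        spec = build_scenario(3, N_E=50, N_I=14)
        cfg1 = SimulationConfig(dt=0.25, duration=600.0,
                                transient_discard=100.0, seed=1)
        cfg2 = replace(cfg1, seed=2)
        a, b = run(spec, cfg1), run(spec, cfg2)
        assert a.spikes["E1"].n_spikes != b.spikes["E1"].n_spikes or \
            not np.array_equal(a.spikes["E1"].times, b.spikes["E1"].times)

    def test_accelerated_and_reference_paths_agree(self):
        # The compiled kernel must reproduce the vectorized reference loop
        # spike for spike.
        spec = build_scenario(3, N_E=40, N_I=12, seed=5)
        cfg = SimulationConfig(dt=0.5, duration=500.0,
                               transient_discard=100.0, seed=5)
        fast = run(spec, cfg)
        ref = run(spec, replace(cfg, accelerated=False))
        for pid in fast.spikes:
            assert np.array_equal(fast.spikes[pid].neuron_ids,
                                  ref.spikes[pid].neuron_ids)
            assert np.allclose(fast.traces[pid].mean_V,
                               ref.traces[pid].mean_V, atol=1e-9)


class TestSingleNeuronIntegration:
    @staticmethod
    def _spike_times(I_const, dt, T=400.0):
        """Mini Heun integrator for one neuron under constant current."""
        p = INHIBITORY_ADEX
        V, w = p.E_L, 0.0
        refr = 0.0
        times = []
        n = int(round(T / dt))
        for k in range(n):
            if refr > 0:
                V = p.V_r
                refr -= dt
                continue

            def f(v, w_):
                arg = min((v - p.V_T) / p.Delta_T, 30.0)
                dV = (-p.g_L * (v - p.E_L)
                      + p.g_L * p.Delta_T * np.exp(arg) - w_ + I_const) / p.C
                return dV, (p.a * (v - p.E_w) - w_) / p.tau_w
            f1V, f1w = f(V, w)
            V1 = min(V + dt * f1V, p.V_peak)
            f2V, f2w = f(V1, w + dt * f1w)
            V += 0.5 * dt * (f1V + f2V)
            w += 0.5 * dt * (f1w + f2w)
            if V >= p.V_peak:
                V = p.V_r
                refr = p.tau_ref
                times.append((k + 1) * dt)
        return np.asarray(times)

    def test_suprathreshold_firing_is_periodic_and_dt_robust(self):
        # Constant current above rheobase: the inter-spike intervals after
        # the first spike are constant, and the period at dt=0.5 ms matches
        # a fine-step reference within 2%.
        t_coarse = self._spike_times(180.0, dt=0.5, T=800.0)
        t_fine = self._spike_times(180.0, dt=0.01, T=800.0)
        isi_c = np.diff(t_coarse)[1:]
        isi_f = np.diff(t_fine)[1:]
        assert isi_c.std() < 1e-9
        assert abs(isi_c.mean() - isi_f.mean()) / isi_f.mean() < 0.02


class TestRecordingsAndGuards:
    def test_membrane_potentials_stay_bounded(self, small_ei_result):
        syn = small_ei_result.spec.synapse
        lo = syn.E_GABA - 30.0
        for pid, tr in small_ei_result.traces.items():
            vpk = small_ei_result.spec.population(pid).adex.V_peak
            assert tr.V.min() >= lo
            assert tr.V.max() <= vpk + 1e-9

    def test_sampling_rate_default_is_2khz(self, small_ei_result):
        assert small_ei_result.fs == pytest.approx(2000.0)

    def test_network_lfp_weights_populations_by_size(self, small_ei_result):
        res = small_ei_result
        nE = res.spec.population("E1").n
        nI = res.spec.population("I1").n
        manual = (nE * res.traces["E1"].mean_V
                  + nI * res.traces["I1"].mean_V) / (nE + nI)
        assert np.allclose(res.network_mean_voltage(1), manual)

    def test_memory_guard_increases_stride(self):
        spec = quiet_two_pop_spec(30)
        cfg = SimulationConfig(dt=0.05, duration=2000.0,
                               transient_discard=0.0, seed=0,
                               n_record_neurons=None, record_stride=1)
        import gammasync.sim_engine as se
        old = se._RECORD_SAMPLE_CAP
        se._RECORD_SAMPLE_CAP = 100_000
        try:
            with pytest.warns(UserWarning, match="stride"):
                res = run(spec, cfg)
        finally:
            se._RECORD_SAMPLE_CAP = old
        assert res.fs < 1000.0 / 0.05

    def test_save_and_load_round_trip(self, small_ei_result, tmp_path):
        save_result(small_ei_result, tmp_path / "out")
        arrays, meta = load_result_traces(tmp_path / "out")
        assert meta["scenario"] == 3
        assert meta["fs"] == small_ei_result.fs
        assert np.allclose(arrays["meanV_E1"],
                           small_ei_result.traces["E1"].mean_V)
        spk = np.loadtxt(tmp_path / "out" / "spikes_I1.txt")
        if spk.size:
            assert spk.reshape(-1, 2).shape[0] == \
                small_ei_result.spikes["I1"].n_spikes

    def test_projection_delay_shifts_delivery(self):
        # With a delayed cross projection the engine still runs and the
        # delayed network receives input (smoke check of the ring buffer;
        # the study's configurations use zero delay).
        spec = build_scenario(3, N_E=40, N_I=12, delta_net=2.0, seed=3)
        cfg = SimulationConfig(dt=0.5, duration=500.0,
                               transient_discard=100.0, seed=3)
        res = run(spec, cfg)
        assert sum(r.n_spikes for r in res.spikes.values()) > 0


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"dt": 0.0}, {"integrator": "rk4"},
        {"duration": 100.0, "transient_discard": 200.0},
    ])
    def test_invalid_config_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
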