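"""Population simulator, controller, pulsatile baseline and metrics."""

import numpy as np
import pytest

from neurodesync.electrode import CircuitParams, StimulusWaveform, simulate_circuit
from neurodesync.population import (
    ControllerState,
    NetworkConfig,
    controller_step,
    energy_metric,
    faradaic_metric,
    initial_states,
    pulsatile_waveform,
    sample_distances,
    simulate_network,
)


class TestSampleDistances:
    def test_homogeneous_unit_scales(self):
        d, s = sample_distances("homogeneous", N=10)
        assert np.all(d == 1.0) and np.all(s == 1.0)

    def test_cubic_law(self):
        d = np.array([1.0, 2.0])
        s = 1.0 / d**3
        _, scale = sample_distances({"law": "uniform", "low": 1.0, "high": 1.0}, N=2, seed=0)
        assert np.allclose(scale, 1.0)
        assert np.allclose(s, [1.0, 0.125])

    def test_seeded_reproducibility(self):
        spec = {"law": "uniform", "low": 0.75, "high": 1.5}
        d1, _ = sample_distances(spec, N=50, seed=9)
        d2, _ = sample_distances(spec, N=50, seed=9)
        assert np.array_equal(d1, d2)

    def test_unsupported_law_rejected(self):
        with pytest.raises(ValueError):
            sample_distances({"law": "cauchy"}, N=5)


class TestPulsatile:
    def test_charge_balance_and_pulse_count(self):
        t, u = pulsatile_waveform(98.0, 0.2, 4.0, 300.0, dt=0.005)
        # rectangle sum; the zeroed turn-on sample balances the endpoint sample
        assert np.sum(u) * (t[1] - t[0]) == pytest.approx(0.0, abs=1e-10)
        # 75 complete cycles of 4 ms in 300 ms (the closing endpoint sample
        # is the onset of what would be cycle 76)
        rises = np.sum((u[:-2] <= 0) & (u[1:-1] > 0))
        assert rises == 75

    def test_zero_amplitude(self):
        _, u = pulsatile_waveform(0.0, 0.2, 4.0, 20.0)
        assert np.max(np.abs(u)) == 0.0

    def test_phase_width_must_fit(self):
        with pytest.raises(ValueError):
            pulsatile_waveform(1.0, 3.0, 4.0, 20.0)

    def test_cathodic_first_is_sign_flip(self):
        t, ua = pulsatile_waveform(1.0, 0.2, 4.0, 8.0, anodic_first=True)
        _, uc = pulsatile_waveform(1.0, 0.2, 4.0, 8.0, anodic_first=False)
        assert np.allclose(ua, -uc)


class TestMetrics:
    def test_zero_waveform(self):
        t = np.arange(0, 10, 0.01)
        z = np.zeros_like(t)
        assert energy_metric((t, z)) == 0.0
        assert faradaic_metric((t, z, z)) == 0.0

    def test_energy_quadratic_scaling(self):
        t = np.arange(0, 10, 0.01)
        u = np.sin(t)
        assert energy_metric((t, 3 * u)) == pytest.approx(9 * energy_metric((t, u)), rel=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            faradaic_metric((np.arange(5), np.arange(4), np.arange(5)))

    def test_grid_refinement_stability(self, circuit):
        vals = []
        for dt in (0.01, 0.005):
            t, u = pulsatile_waveform(98.0, 0.2, 4.0, 40.0, dt=dt)
            wf = simulate_circuit(t, u, circuit)
            vals.append(energy_metric(wf))
        assert abs(vals[1] - vals[0]) < 5e-3 * vals[0]


class TestController:
    def _step(self, state, t, v, v_prev):
        return controller_step(state, t, v, v_prev, stim_len=10, lockout=12.0)

    def test_rising_crossing_does_not_trigger(self):
        s = ControllerState()
        fired = self._step(s, 0.01, -44.0, -46.0)  # crossing with positive slope
        assert not fired

    def test_single_trigger_at_first_falling_sample(self):
        s = ControllerState()
        self._step(s, 0.01, -44.0, -46.0)   # enter excursion, rising
        f1 = self._step(s, 0.02, -43.0, -44.0)  # still rising
        f2 = self._step(s, 0.03, -43.5, -43.0)  # crest passed -> trigger
        f3 = self._step(s, 0.04, -44.0, -43.5)  # same excursion -> no retrigger
        assert (f1, f2, f3) == (False, True, False)

    def test_inactive_requires_rearm_above_minus_40(self):
        s = ControllerState(mode="inactive")
        self._step(s, 0.01, -41.0, -46.0)
        assert s.mode == "inactive"
        self._step(s, 0.02, -39.5, -41.0)
        assert s.mode == "active"

    def test_goes_inactive_after_quiet_lockout(self):
        s = ControllerState()
        s.watch_deadline = 5.0
        self._step(s, 6.0, -60.0, -60.0)
        assert s.mode == "inactive"


class TestSimulateNetwork:
    def test_uncoupled_deterministic_pair_keeps_phase_offsets(self, lc, params):
        cfg = NetworkConfig(N=3, sigma=0.0, noise_2D=0.0, seed=2, duration=84.0, dt=0.01)
        tr = simulate_network(cfg, "none", lc=lc, params=params)
        # spike-time differences of the tracked pair drift < 1e-3 ms over 10 periods
        s0 = [t for i, t in tr.raster if i == 0]
        s1 = [t for i, t in tr.raster if i == 1]
        n = min(len(s0), len(s1))
        d = np.array(s0[:n]) - np.array(s1[:n])
        assert abs(d[-1] - d[0]) < 1e-3

    def test_matches_adaptive_solver_without_noise(self, lc, params):
        """Fixed-step Heun at dt=0.01 reproduces the adaptive-solver spike
        times within 1e-2 ms over ten periods."""
        from neurodesync.neuron import simulate_single

        x0 = lc.orbit(np.array([0.5]))
        cfg = NetworkConfig(N=2, sigma=0.0, noise_2D=0.0, seed=0, duration=84.0, dt=0.01)
        tr = simulate_network(cfg, "none", lc=lc, params=params, init=np.vstack([x0, x0]))
        heun_spikes = np.array([t for i, t in tr.raster if i == 0])
        _, _, ref_spikes = simulate_single(
            params, t_span=(0, 84.0), x0=x0[0], rtol=1e-10, n_samples=84001
        )
        n = min(heun_spikes.size, ref_spikes.size)
        assert n >= 9
        assert np.max(np.abs(heun_spikes[:n] - ref_spikes[:n])) < 1e-2

    def test_noise_scaling_of_short_horizon_variance(self, lc, params):
        """Var of V about the deterministic path grows linearly in 2D."""
        x0 = lc.orbit(np.zeros(40))
        out = {}
        for twoD in (0.35, 0.7, 1.4):
            cfg = NetworkConfig(
                N=40, sigma=0.0, noise_2D=twoD, seed=123, duration=1.0, dt=0.01,
                record_every=100, phase_jitter_sd=0.0,
            )
            tr = simulate_network(cfg, "none", lc=lc, params=params, init=x0)
            out[twoD] = np.var(tr.V[-1])
        r1 = out[0.7] / out[0.35]
        r2 = out[1.4] / out[0.7]
        assert r1 == pytest.approx(2.0, rel=0.45)
        assert r2 == pytest.approx(2.0, rel=0.45)

    def test_mean_voltage_is_population_mean(self, lc, params):
        cfg = NetworkConfig(N=10, sigma=0.07, noise_2D=0.0, seed=1, duration=5.0,
                            dt=0.01, record_every=1)
        tr = simulate_network(cfg, "none", lc=lc, params=params)
        assert np.allclose(tr.v_mean[::100], tr.V[::100].mean(axis=1), atol=1e-12)

    def test_coupling_conserves_population_mean_input(self):
        rng = np.random.default_rng(0)
        V = rng.normal(-60, 5, 100)
        coupling = 0.07 * (V.mean() - V)
        assert abs(coupling.sum()) < 1e-10

    def test_synchronized_coupled_network_stays_synchronized(self, lc, params):
        cfg = NetworkConfig(N=50, sigma=0.07, noise_2D=0.0, seed=7, duration=60.0, dt=0.01)
        tr = simulate_network(cfg, "none", lc=lc, params=params)
        late = np.array([t for _, t in tr.raster if t > 50.0])
        # all late spikes cluster into tight volleys: nearest-volley spread < 0.5 ms
        late.sort()
        gaps = np.diff(late)
        volley_breaks = gaps > 2.0
        assert late.size >= 50
        assert np.max(gaps[~volley_breaks]) < 0.5

    def test_requires_initialization_source(self, params):
        cfg = NetworkConfig(N=5, duration=1.0)
        with pytest.raises(ValueError):
            simulate_network(cfg, "none", params=params)

    def test_rejects_coarse_time_step(self, lc, params):
        cfg = NetworkConfig(N=5, duration=1.0, dt=0.05)
        with pytest.raises(ValueError):
            simulate_network(cfg, "none", lc=lc, params=params)


class TestEventControlIntegration:
    def test_event_run_triggers_and_injects_energy(self, lc, params, design_g8, circuit):
        cfg = NetworkConfig(N=40, sigma=0.07, noise_2D=0.0, seed=4, duration=60.0, dt=0.01)
        tr = simulate_network(cfg, "event", circuit, stimulus=design_g8.waveform,
                              lc=lc, params=params)
        trig = [e for e in tr.events if e[0] == "trigger"]
        assert len(trig) >= 2
        assert energy_metric((tr.t_full, tr.u_e)) > 1.0

    def test_heterogeneous_distances_desynchronize_at_least_as_fast(
        self, lc, params, design_g8, circuit
    ):
        """Neurons spread over 0.75-1.5 mm receive heterogeneous effective
        inputs, which can only hasten loss of synchrony relative to the
        homogeneous worst case (same seed and stimulus)."""
        from neurodesync.lyapunov import _ballistic_phases

        def dispersion(distances, seed):
            cfg = NetworkConfig(
                N=40, sigma=0.07, noise_2D=0.0, seed=seed, duration=80.0, dt=0.01,
                distances=distances, record_every=100,
            )
            tr = simulate_network(cfg, "event", circuit, stimulus=design_g8.waveform,
                                  lc=lc, params=params, tracked_idx=tuple(range(8)))
            ph = _ballistic_phases(tr.tracked[-1], params, lc.T)
            return 1.0 - np.abs(np.mean(np.exp(1j * ph)))  # circular dispersion

        seeds = (5, 12, 31)
        het, hom = [], []
        for s in seeds:
            d_het, _ = sample_distances(
                {"law": "uniform", "low": 0.75, "high": 1.5}, N=40, seed=s
            )
            het.append(dispersion(d_het, s))
            hom.append(dispersion("homogeneous", s))
        assert np.median(het) >= np.median(hom)
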