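"""Euler-Lagrange system, shooting and collocation design tests."""

import numpy as np
import pytest

from neurodesync.design import (
    ControlWeights,
    cost_functional,
    design_stimulus,
    double_bisection,
    el_rhs,
    shoot,
)
from neurodesync.electrode import CircuitParams, simulate_circuit


class TestControlWeights:
    def test_singular_problem_rejected(self):
        with pytest.raises(ValueError):
            ControlWeights(alpha=0.0)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            ControlWeights(gamma=-1.0)


class TestElRhs:
    def test_unforced_phase_velocity_is_omega(self, prc, lc, circuit):
        w = ControlWeights()
        state = np.array([0.3, -0.2, 1.7, 0.0, 0.0, 0.0])  # u_e = 0, lambdas = 0
        d = el_rhs(state, w, prc, lc, circuit)
        assert d[2] == pytest.approx(lc.omega, rel=1e-14)

    def test_coupling_term_only_changes_multiplier_channel(self, prc, lc, circuit):
        state = np.array([0.5, 0.1, 2.0, 0.8, 3.0, -2.0])
        d0 = el_rhs(state, ControlWeights(sigma=0.0), prc, lc, circuit)
        d1 = el_rhs(state, ControlWeights(sigma=0.07), prc, lc, circuit)
        diff = np.abs(d1 - d0)
        assert diff[5] > 0  # lambda2 channel gains the coupling term
        assert np.max(diff[[0, 1, 2, 3, 4]]) < 1e-14

    def test_circuit_equation_enforced_along_solution(self, prc, lc, circuit, design_g8):
        """Along the designed solution, u_e and u_p satisfy the electrode ODE."""
        wf = design_g8.waveform
        resim = simulate_circuit(wf.t, wf.u_p, circuit, u_e0=wf.u_e[0])
        scale = np.max(np.abs(wf.u_e))
        assert np.max(np.abs(resim.u_e - wf.u_e)) < 1e-4 * scale


class TestShooting:
    def test_zero_multipliers_solve_reward_free_problem(self, prc, lc, circuit):
        """With beta=0 every cost term is nonnegative, so u=0 (all-zero
        trajectory) is optimal and the zero multipliers hit the terminal
        conditions exactly."""
        w = ControlWeights(beta=0.0, gamma=8.0)
        r1, r2 = shoot(0.0, 0.0, w, prc, lc, circuit)
        assert abs(r1) < 1e-9 and abs(r2) < 1e-9

    def test_rejects_non_finite_multipliers(self, prc, lc, circuit):
        with pytest.raises(ValueError):
            shoot(np.nan, 0.0, ControlWeights(), prc, lc, circuit)

    def test_blowup_returns_flagged_sentinel(self, prc, lc, circuit):
        r1, r2 = shoot(150.0, 150.0, ControlWeights(), prc, lc, circuit, rtol=1e-6)
        assert abs(r1) >= 1e12 and abs(r2) >= 1e12

    def test_residuals_continuous_on_scan_grid(self, prc, lc, circuit):
        """Residual sign scan used for bracket seeding contains no NaNs."""
        w = ControlWeights(beta=0.0)
        grid = np.linspace(-20, 20, 4)
        res = np.array([shoot(a, b, w, prc, lc, circuit, rtol=1e-6) for a in grid for b in grid])
        assert np.all(np.isfinite(res))

    def test_double_bisection_finds_trivial_root(self, prc, lc, circuit):
        w = ControlWeights(beta=0.0)
        roots = double_bisection(
            w, prc, lc, circuit,
            bracket_box=((-5.0, 5.0), (-5.0, 5.0)), n_scan=3, tol=1e-6, rtol=1e-6,
        )
        best = min(roots, key=lambda r: abs(r[0]) + abs(r[1]))
        assert abs(best[0]) < 1e-5 and abs(best[1]) < 1e-5


class TestDesignStimulus:
    def test_boundary_conditions_met(self, design_g8):
        wf = design_g8.waveform
        scale = np.max(np.abs(wf.u_p))
        assert abs(wf.u_p[-1]) < 1e-6 * scale
        assert abs(wf.u_e[-1]) < 1e-6 * scale
        assert abs(wf.u_p[0]) < 1e-12 and abs(wf.u_e[0]) < 1e-12

    def test_positive_finite_time_exponent(self, design_g8):
        assert design_g8.Lambda > 0

    def test_design_is_reproducible_from_perturbed_guess(self, phase_model, design_g8, circuit):
        """Re-solving from a rescaled initial iterate lands on the same
        waveform (basin stability of the branch)."""
        _, lc, prc = phase_model
        perturbed = design_stimulus(
            ControlWeights(gamma=8.0), prc, lc, circuit, initial_guess=design_g8
        )
        num = np.max(np.abs(perturbed.waveform.u_e - design_g8.waveform.u_e))
        assert num < 1e-4 * np.max(np.abs(design_g8.waveform.u_e))

    def test_gamma_zero_beats_gamma_heavy_on_exponent(self, phase_model, circuit, design_g8):
        from neurodesync.workbench import get_design

        d0 = get_design(0.0)
        assert d0.Lambda > design_g8.Lambda

    def test_amplitude_cap_rejection(self, phase_model, circuit):
        _, lc, prc = phase_model
        with pytest.raises(RuntimeError):
            design_stimulus(ControlWeights(gamma=8.0), prc, lc, circuit, u_cap=0.5)


class TestCostFunctional:
    def test_zero_waveform_has_zero_cost(self, prc, lc, circuit):
        from neurodesync.electrode import StimulusWaveform

        t = np.linspace(0, 8.02, 401)
        wf = StimulusWaveform(t=t, u_p=np.zeros_like(t), u_e=np.zeros_like(t))
        total, terms = cost_functional(wf, prc, ControlWeights(), lc, circuit)
        assert total == 0.0 and all(v == 0.0 for v in terms.values())

    def test_gamma_scaling_is_exact(self, prc, lc, circuit, design_g8):
        wf = design_g8.waveform
        w1 = ControlWeights(gamma=8.0)
        w2 = ControlWeights(gamma=16.0)
        c1, t1 = cost_functional(wf, prc, w1, lc, circuit)
        c2, t2 = cost_functional(wf, prc, w2, lc, circuit)
        assert c2 - c1 == pytest.approx(t1["faradaic"], rel=1e-9)

    def test_inconsistent_pair_rejected(self, prc, lc, circuit, design_g8):
        from neurodesync.electrode import StimulusWaveform

        wf = design_g8.waveform
        bad = StimulusWaveform(t=wf.t, u_p=wf.u_p, u_e=wf.u_e + 0.5)
        with pytest.raises(ValueError):
            cost_functional(bad, prc, ControlWeights(gamma=8.0), lc, circuit)

    def test_designed_stimulus_is_local_minimum(self, prc, lc, circuit, design_g8, rng):
        """No admissible smooth perturbation (fixed endpoints, circuit-
        consistent, preserving u_e(t1)=0) lowers the cost."""
        wf = design_g8.waveform
        w = design_g8.weights
        t = wf.t
        base_cost, _ = cost_functional(wf, prc, w, lc, circuit)
        # circuit response of each sine mode, for the terminal-field constraint
        modes = [np.sin((k + 1) * np.pi * t / t[-1]) for k in range(8)]
        mode_end = [simulate_circuit(t, m, circuit).u_e[-1] for m in modes]
        scale = 0.03 * np.max(np.abs(wf.u_p))
        improved = 0
        for _ in range(200):
            c = rng.normal(size=8)
            delta = sum(ci * m for ci, m in zip(c, modes))
            # project out the terminal-field component (linear circuit)
            end = sum(ci * e for ci, e in zip(c, mode_end))
            delta = delta - (end / mode_end[0]) * modes[0]
            delta *= scale / max(np.max(np.abs(delta)), 1e-12)
            u_p = wf.u_p + delta
            pe = simulate_circuit(t, u_p, circuit)
            from neurodesync.electrode import StimulusWaveform

            cand = StimulusWaveform(t=t, u_p=u_p, u_e=pe.u_e)
            cost, _ = cost_functional(cand, prc, w, lc, circuit)
            if cost < base_cost - 1e-9 * abs(base_cost):
                improved += 1
        assert improved == 0

    def test_coupled_and_uncoupled_designs_nearly_identical(self, phase_model, circuit, design_g8):
        _, lc, prc = phase_model
        coupled = design_stimulus(
            ControlWeights(gamma=8.0, sigma=0.07), prc, lc, circuit,
            coupled=True, initial_guess=design_g8,
        )
        rel = np.max(np.abs(coupled.waveform.u_e - design_g8.waveform.u_e)) / np.max(
            np.abs(design_g8.waveform.u_e)
        )
        assert rel < 0.05
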