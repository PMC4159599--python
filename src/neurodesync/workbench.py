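"""Experiment orchestration: reproducible end-to-end studies.

Each named experiment wires the pipeline modules together with the default
(Table-style) parameter set and a single root seed, and returns a
machine-readable result bundle.  The heavy shared artifacts (limit cycle,
PRC, designed stimuli) are memoized per process so a sweep of experiments
pays for them once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from neurodesync.design import ControlWeights, DesignResult, design_stimulus
from neurodesync.electrode import CircuitParams, StimulusWaveform, simulate_circuit
from neurodesync.lyapunov import (
    exponent_coupled_approx,
    exponent_uncoupled,
    numerical_exponent,
)
from neurodesync.neuron import NeuronParams
from neurodesync.phase import compute_prc, find_limit_cycle
from neurodesync.population import (
    NetworkConfig,
    energy_metric,
    faradaic_metric,
    initial_states,
    pulsatile_waveform,
    sample_distances,
    simulate_network,
)

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "generate_fixtures",
    "get_phase_model",
    "get_design",
    "EXPERIMENTS",
]

GAMMA_SWEEP = (0.0, 8.0, 32.0, 64.0, 120.0, 180.0)
TABLE2_GAMMAS = (8.0, 64.0, 180.0)


@dataclass
class ExperimentConfig:
    """A named experiment with parameter overrides and a root seed."""

    name: str
    seed: int = 1
    overrides: dict = field(default_factory=dict)
    output_dir: str | Path | None = None


@lru_cache(maxsize=4)
def get_phase_model(grid_size: int = 512):
    """Memoized (params, limit cycle, PRC) for the default neuron."""
    params = NeuronParams()
    lc = find_limit_cycle(params, grid_size=grid_size)
    prc = compute_prc(lc, params)
    return params, lc, prc


_DESIGN_CACHE: dict[tuple, DesignResult] = {}


def get_design(gamma: float, coupled: bool = False, sigma: float = 0.07) -> DesignResult:
    """Memoized locally optimal stimulus for the default weights at ``gamma``.

    Designs are warm-started from the cached design nearest in gamma
    (continuation), which keeps a sweep over gamma fast and on one branch.
    """
    key = (float(gamma), bool(coupled), float(sigma) if coupled else 0.0)
    if key in _DESIGN_CACHE:
        return _DESIGN_CACHE[key]
    params, lc, prc = get_phase_model()
    w = ControlWeights(gamma=float(gamma), sigma=sigma if coupled else 0.0)
    guess = None
    if _DESIGN_CACHE:
        nearest = min(_DESIGN_CACHE, key=lambda k: abs(k[0] - gamma) + 50.0 * (k[1] != coupled))
        guess = _DESIGN_CACHE[nearest]
    res = design_stimulus(w, prc, lc, CircuitParams(), coupled=coupled, initial_guess=guess)
    _DESIGN_CACHE[key] = res
    return res


def _exp_gamma_sweep(seed: int, overrides: dict) -> dict:
    gammas = overrides.get("gammas", GAMMA_SWEEP)
    rows = []
    for gm in gammas:
        d = get_design(float(gm))
        rows.append(
            {
                "gamma": float(gm),
                "Lambda_T": d.Lambda,
                "Lambda_c_T": d.Lambda_c,
                "max_abs_u_e": float(np.max(np.abs(d.waveform.u_e))),
                "cost": d.cost,
                **{f"cost_{k}": v for k, v in d.cost_terms.items()},
            }
        )
    return {"rows": rows, "strictly_decreasing": all(
        rows[i]["Lambda_T"] > rows[i + 1]["Lambda_T"] for i in range(len(rows) - 1)
    )}


def _exp_event_control(seed: int, overrides: dict) -> dict:
    params, lc, prc = get_phase_model()
    d = get_design(float(overrides.get("gamma", 8.0)))
    cfg = NetworkConfig(
        seed=seed,
        duration=float(overrides.get("duration", 300.0)),
        noise_2D=float(overrides.get("noise_2D", 0.7)),
        dt=float(overrides.get("dt", 0.01)),
    )
    trace = simulate_network(cfg, "event", CircuitParams(), stimulus=d.waveform, lc=lc, params=params)
    n_trig = sum(1 for e in trace.events if e[0] == "trigger")
    return {
        "energy": energy_metric((trace.t_full, trace.u_e)),
        "faradaic": faradaic_metric((trace.t_full, trace.u_p, trace.u_e)),
        "n_triggers": n_trig,
        "n_spikes": len(trace.raster),
        "events": [(k, float(t)) for k, t in trace.events],
    }


def _exp_pulsatile(seed: int, overrides: dict) -> dict:
    dt = float(overrides.get("dt", 0.005))
    t, u_p = pulsatile_waveform(
        amplitude=float(overrides.get("amplitude", 98.0)),
        phase_width_ms=float(overrides.get("phase_width_ms", 0.2)),
        period_ms=float(overrides.get("period_ms", 4.0)),
        duration_ms=float(overrides.get("duration", 300.0)),
        dt=dt,
    )
    wf = simulate_circuit(t, u_p, CircuitParams())
    return {
        "energy": energy_metric(wf),
        "faradaic": faradaic_metric(wf),
        "n_pulses": int(round(float(overrides.get("duration", 300.0)) / float(overrides.get("period_ms", 4.0)))),
    }


def _exp_faradaic(seed: int, overrides: dict) -> dict:
    ev = _exp_event_control(seed, overrides)
    pu = _exp_pulsatile(seed, overrides)
    return {
        "event_energy": ev["energy"],
        "event_faradaic": ev["faradaic"],
        "pulsatile_energy": pu["energy"],
        "pulsatile_faradaic": pu["faradaic"],
        "energy_ratio": pu["energy"] / max(ev["energy"], 1e-300),
    }


def _exp_sync_validation(seed: int, overrides: dict) -> dict:
    """Noise-free, stimulus-free coupled network: phase differences contract
    at the coupling-only exponent predicted by the phase model."""
    params, lc, prc = get_phase_model()
    duration = float(overrides.get("duration", 150.0))
    cfg = NetworkConfig(
        N=int(overrides.get("N", 100)),
        seed=seed,
        duration=duration,
        noise_2D=0.0,
        dt=float(overrides.get("dt", 0.01)),
        record_every=int(overrides.get("record_every", 50)),
    )
    trace = simulate_network(cfg, "none", CircuitParams(), lc=lc, params=params)
    fit = numerical_exponent(trace.t, trace.tracked, params, lc.T, phi_max=np.inf)
    lam_pred = exponent_coupled_approx(None, cfg.sigma, lc, prc, tau=lc.T)
    return {
        "Lambda_c_predicted": lam_pred,
        "Lambda_fitted": fit.Lambda,
        "fit_r_squared": fit.r_squared,
    }


def _exp_coupled_design(seed: int, overrides: dict) -> dict:
    gamma = float(overrides.get("gamma", 8.0))
    sigma = float(overrides.get("sigma", 0.07))
    du = get_design(gamma, coupled=False)
    dc = get_design(gamma, coupled=True, sigma=sigma)
    scale = float(np.max(np.abs(du.waveform.u_e)))
    rel = float(np.max(np.abs(du.waveform.u_e - dc.waveform.u_e)) / scale)
    return {
        "gamma": gamma,
        "sigma": sigma,
        "max_norm_relative_difference": rel,
        "Lambda_uncoupled_design": du.Lambda,
        "Lambda_coupled_design": dc.Lambda,
    }


def _run_table2_row(gamma: float, seed: int, overrides: dict) -> dict:
    params, lc, prc = get_phase_model()
    d = get_design(gamma)
    sigma = float(overrides.get("sigma", 0.07))
    cfg = NetworkConfig(
        N=int(overrides.get("N", 100)),
        seed=seed,
        duration=float(overrides.get("duration", 150.0)),
        noise_2D=0.0,
        dt=float(overrides.get("dt", 0.01)),
        record_every=int(overrides.get("record_every", 50)),
    )
    trace = simulate_network(cfg, "event", CircuitParams(), stimulus=d.waveform, lc=lc, params=params)
    fit = numerical_exponent(trace.t, trace.tracked, params, lc.T)
    return {
        "gamma": gamma,
        "Lambda_T": d.Lambda,
        "Lambda_c_T": d.Lambda_c,
        "Lambda_fitted": fit.Lambda,
        "fit_r_squared": fit.r_squared,
        "exponential": fit.exponential,
    }


def _exp_table2(seed: int, overrides: dict) -> dict:
    gammas = overrides.get("gammas", TABLE2_GAMMAS)
    return {"rows": [_run_table2_row(float(g), seed, overrides) for g in gammas]}


EXPERIMENTS = {
    "fig4_gamma_sweep": _exp_gamma_sweep,
    "fig5_event_control": _exp_event_control,
    "fig6_pulsatile": _exp_pulsatile,
    "fig7_faradaic": _exp_faradaic,
    "fig8_sync_validation": _exp_sync_validation,
    "fig9_coupled_design": _exp_coupled_design,
    "fig10_table2": _exp_table2,
}


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run a named experiment; deterministic given its seed.

    Writes ``<name>.json`` into ``cfg.output_dir`` when set.  Unknown names
    raise with the list of valid experiments.
    """
    if cfg.name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {cfg.name!r}; valid: {sorted(EXPERIMENTS)}")
    result = EXPERIMENTS[cfg.name](cfg.seed, cfg.overrides)
    bundle = {"experiment": cfg.name, "seed": cfg.seed, "overrides": cfg.overrides, "result": result}
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{cfg.name}.json").write_text(json.dumps(bundle, indent=1, sort_keys=True))
    return bundle


def generate_fixtures(kind: str, params: dict | None = None, seed: int = 0) -> dict:
    """Seeded synthetic fixtures used by the test suite (no external data).

    kinds: "phases" (initial near-synchronous phase samples), "distances"
    (neuron-probe distances + input scale factors), "waveform" (a unit
    charge-balanced biphasic train).
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "phases":
        n = int(params.get("N", 100))
        jitter = float(params.get("jitter_sd", 0.1))
        return {"phases": np.mod(rng.normal(0.0, jitter, n), 2 * np.pi)}
    if kind == "distances":
        spec = params.get("spec", "homogeneous")
        d, scale = sample_distances(spec, int(params.get("N", 100)), seed)
        return {"distances": d, "scale": scale}
    if kind == "waveform":
        t, u_p = pulsatile_waveform(
            amplitude=float(params.get("amplitude", 1.0)),
            phase_width_ms=float(params.get("phase_width_ms", 0.2)),
            period_ms=float(params.get("period_ms", 4.0)),
            duration_ms=float(params.get("duration_ms", 20.0)),
        )
        return {"t": t, "u_p": u_p}
    raise ValueError(f"unknown fixture kind {kind!r}")
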