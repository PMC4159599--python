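"""Stochastic coupled-population simulation with the electrode in the loop.

N identical thalamic neurons, all-to-all electrotonic coupling of strength
sigma (mean-field voltage-difference coupling), independent Gaussian white
noise of intensity 2D in each voltage equation, and a shared extracellular
field input u_e produced by the probe circuit.  Neurons at distance d_i from
the probe receive the field input scaled by F(d_i)/F(1) = 1/d_i^3.

Integration is fixed-step stochastic Heun (second-order stochastic
Runge-Kutta for additive noise): the Euler-Maruyama predictor and the
trapezoidal drift corrector share one Wiener increment per step.  The
deterministic circuit state is advanced inside the same two-stage update.

The event-based controller mimics a closed-loop implant: it watches the mean
voltage and plays one pre-designed stimulus at a time, triggered on a
falling mean-voltage excursion above -45 mV, disarming when the population
stays quiet and re-arming when the mean voltage again reaches -40 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from neurodesync.electrode import CircuitParams, StimulusWaveform
from neurodesync.neuron import NeuronParams, SPIKE_THRESHOLD_MV, _rhs
from neurodesync.phase import LimitCycle

__all__ = [
    "NetworkConfig",
    "ControllerState",
    "PopulationTrace",
    "simulate_network",
    "controller_step",
    "pulsatile_waveform",
    "energy_metric",
    "faradaic_metric",
    "sample_distances",
    "initial_states",
]

TRIGGER_MV = -45.0
REARM_MV = -40.0


@dataclass
class NetworkConfig:
    """Population and integration settings.

    ``noise_2D`` is the variance parameter 2D of the white noise (0.7 by
    default); ``distances`` may be "homogeneous" or an explicit array of
    probe distances in mm.
    """

    N: int = 100
    sigma: float = 0.07
    noise_2D: float = 0.7
    distances: str | np.ndarray = "homogeneous"
    seed: int = 0
    dt: float = 0.01
    duration: float = 300.0
    phase_jitter_sd: float = 0.1
    record_every: int = 10
    lockout_periods: float = 1.5

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population needs at least two neurons")
        if self.sigma < 0 or self.noise_2D < 0:
            raise ValueError("sigma and noise intensity must be nonnegative")


@dataclass
class ControllerState:
    """Two-state (active/inactive) event-based controller bookkeeping."""

    mode: str = "active"
    playing: bool = False
    play_idx: int = 0
    in_excursion: bool = False
    triggered_this_excursion: bool = False
    watch_deadline: float | None = None  # inactivity check after stimulus end
    events: list = field(default_factory=list)


def controller_step(
    state: ControllerState,
    t: float,
    v_mean: float,
    v_mean_prev: float,
    stim_len: int,
    lockout: float,
) -> bool:
    """Advance the controller one sample; return True when a stimulus starts.

    Trigger rule (active mode, no stimulus playing): the first sample with
    negative mean-voltage slope inside an excursion above -45 mV.  After a
    stimulus ends, if no new upward crossing of -45 mV occurs within the
    lockout window the controller goes inactive; it re-arms when the mean
    voltage registers above -40 mV.
    """
    crossed_up = v_mean_prev < TRIGGER_MV <= v_mean
    if crossed_up:
        state.in_excursion = True
        state.triggered_this_excursion = False
        state.watch_deadline = None  # population still spiking above threshold
    if v_mean < TRIGGER_MV:
        state.in_excursion = False
        state.triggered_this_excursion = False

    if state.mode == "inactive":
        if v_mean > REARM_MV:
            state.mode = "active"
            state.events.append(("rearm", t))
        return False

    if state.watch_deadline is not None and t > state.watch_deadline:
        state.mode = "inactive"
        state.watch_deadline = None
        state.events.append(("inactive", t))
        return False

    if (
        state.in_excursion
        and not state.triggered_this_excursion
        and v_mean < v_mean_prev
    ):
        # every qualifying crossing triggers a new stimulus; a playback in
        # progress is restarted (at most one stimulus plays at a time)
        state.events.append(("retrigger" if state.playing else "trigger", t))
        state.playing = True
        state.play_idx = 0
        state.triggered_this_excursion = True
        state.watch_deadline = None
        return True
    return False


@dataclass
class PopulationTrace:
    """Recorded simulation output."""

    t: np.ndarray                 # recorded sample times
    V: np.ndarray                 # (n_rec, N) voltages
    v_mean: np.ndarray            # mean voltage at every integration step
    t_full: np.ndarray            # integration-step times (for v_mean, u traces)
    u_p: np.ndarray               # applied probe input per step
    u_e: np.ndarray               # circuit field input per step
    raster: list                  # (neuron index, spike time) pairs
    tracked: np.ndarray           # (n_rec, n_tracked, 3) full states of tracked neurons
    tracked_idx: tuple
    events: list
    config: NetworkConfig


def sample_distances(
    spec: str | dict = "homogeneous",
    N: int = 100,
    seed: int = 0,
    probe_radius: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded neuron-probe distances (mm) and input scale factors F(d)/F(1).

    ``spec`` is "homogeneous" (all at 1 mm) or a dict like
    ``{"law": "uniform", "low": 0.75, "high": 1.5}``.
    """
    if isinstance(spec, str):
        if spec != "homogeneous":
            raise ValueError(f"unsupported distance spec {spec!r}")
        d = np.ones(N)
    else:
        rng = np.random.default_rng(seed)
        law = spec.get("law")
        if law == "uniform":
            d = rng.uniform(spec["low"], spec["high"], size=N)
        elif law == "lognormal":
            d = rng.lognormal(spec.get("mean", 0.0), spec.get("sd", 0.2), size=N)
        else:
            raise ValueError(f"unsupported distance law {law!r}")
    if np.any(d <= probe_radius):
        raise ValueError("sampled distances must exceed the probe radius")
    return d, 1.0 / d**3


def initial_states(lc: LimitCycle, N: int, jitter_sd: float = 0.1, seed: int = 0) -> np.ndarray:
    """Near-synchronous initial conditions: orbit states at phases ~ N(0, jitter_sd)."""
    rng = np.random.default_rng(seed)
    phases = np.mod(rng.normal(0.0, jitter_sd, size=N), 2.0 * np.pi)
    return lc.orbit(phases)


def pulsatile_waveform(
    amplitude: float = 98.0,
    phase_width_ms: float = 0.2,
    period_ms: float = 4.0,
    duration_ms: float = 300.0,
    dt: float = 0.005,
    anodic_first: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Charge-balanced biphasic pulse train u_p(t) (probe input, u-units).

    Each cycle is +A for one phase width, -A for the next, then zero for the
    rest of the period (sign order flipped when ``anodic_first`` is False);
    the net charge per cycle is zero by construction.
    """
    if 2.0 * phase_width_ms > period_ms:
        raise ValueError("two phase widths must fit inside one period")
    t = np.arange(0.0, duration_ms + 0.5 * dt, dt)
    # epsilon guards against float-mod misclassifying samples that land
    # exactly on phase boundaries
    tau = np.mod(t + 1e-9, period_ms)
    u_p = np.where(tau < phase_width_ms, amplitude, np.where(tau < 2 * phase_width_ms, -amplitude, 0.0))
    # the train switches on at t=0: the sampled (piecewise-linear) drive needs
    # a rising edge there, like every later cycle gets from its preceding
    # zero sample -- otherwise the capacitive step is silently lost
    u_p[0] = 0.0
    if not anodic_first:
        u_p = -u_p
    return t, u_p


def energy_metric(waveform: StimulusWaveform | tuple) -> float:
    """Total injected energy int u_e^2 dt (u-units squared times ms)."""
    t, u_e = (waveform.t, waveform.u_e) if isinstance(waveform, StimulusWaveform) else waveform
    return float(np.trapezoid(np.asarray(u_e) ** 2, np.asarray(t)))


def faradaic_metric(waveform: StimulusWaveform | tuple, R_ct: float = 2e5) -> float:
    """Total Faradaic transfer int |u_p - u_e| / R_ct dt."""
    if isinstance(waveform, StimulusWaveform):
        t, u_p, u_e = waveform.t, waveform.u_p, waveform.u_e
    else:
        t, u_p, u_e = waveform
    t, u_p, u_e = map(np.asarray, (t, u_p, u_e))
    if t.shape != u_p.shape or t.shape != u_e.shape:
        raise ValueError("grid mismatch between t, u_p and u_e")
    return float(np.trapezoid(np.abs(u_p - u_e), t) / R_ct)


def _resample_stimulus(stim: StimulusWaveform, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """Stimulus probe drive and its derivative on the simulation step grid."""
    n = int(round(stim.duration / dt)) + 1
    tg = np.arange(n) * dt
    u_p = np.interp(tg, stim.t - stim.t[0], stim.u_p)
    du_p = np.gradient(u_p, dt)
    return u_p, du_p


def simulate_network(
    cfg: NetworkConfig,
    stimulus_source: str = "none",
    circuit: CircuitParams | None = None,
    stimulus: StimulusWaveform | None = None,
    lc: LimitCycle | None = None,
    params: NeuronParams | None = None,
    init: np.ndarray | None = None,
    tracked_idx: tuple = (0, 1),
    pulsatile_kwargs: dict | None = None,
) -> PopulationTrace:
    """Simulate the coupled noisy population under a stimulation protocol.

    ``stimulus_source`` is "none", "event" (event-based playback of
    ``stimulus`` through the live circuit) or "pulsatile" (continuously
    applied biphasic train built from ``pulsatile_kwargs``).  Initial states
    come from ``init`` or from near-synchronous samples of ``lc``.
    """
    if circuit is None:
        circuit = CircuitParams()
    if params is None:
        params = NeuronParams()
    if cfg.dt > 0.02:
        raise ValueError("dt must resolve the spike upstroke (<= 0.02 ms)")
    rng = np.random.default_rng(cfg.seed)

    if init is not None:
        X = np.array(init, dtype=float)
    else:
        if lc is None:
            raise ValueError("provide either init states or a limit cycle for initialization")
        X = initial_states(lc, cfg.N, cfg.phase_jitter_sd, cfg.seed)
    if X.shape != (cfg.N, 3):
        raise ValueError(f"initial states must be (N, 3), got {X.shape}")

    if isinstance(cfg.distances, str):
        _, scale = sample_distances(cfg.distances, cfg.N, cfg.seed)
    else:
        d = np.asarray(cfg.distances, dtype=float)
        scale = 1.0 / d**3

    n_steps = int(round(cfg.duration / cfg.dt))
    dt = cfg.dt
    sq_noise = np.sqrt(cfg.noise_2D * dt) / params.C

    # stimulus machinery
    if stimulus_source == "pulsatile":
        t_full_grid = np.arange(n_steps + 1) * dt
        pk = dict(amplitude=98.0, phase_width_ms=0.2, period_ms=4.0)
        if pulsatile_kwargs:
            pk.update(pulsatile_kwargs)
        _, up_sched = pulsatile_waveform(duration_ms=cfg.duration, dt=dt, **pk)
        up_sched = up_sched[: n_steps + 1]
        dup_sched = np.gradient(up_sched, dt)
        stim_len = 0
    elif stimulus_source == "event":
        if stimulus is None:
            raise ValueError("event-based control needs a designed stimulus waveform")
        stim_up, stim_dup = _resample_stimulus(stimulus, dt)
        stim_len = stim_up.size
        up_sched = None
    elif stimulus_source == "none":
        up_sched = None
        stim_len = 0
    else:
        raise ValueError(f"unknown stimulus source {stimulus_source!r}")

    ctrl = ControllerState()
    lockout = cfg.lockout_periods * (lc.T if lc is not None else 8.3956)

    n_rec = n_steps // cfg.record_every + 1
    rec_t = np.empty(n_rec)
    rec_V = np.empty((n_rec, cfg.N))
    rec_tracked = np.empty((n_rec, len(tracked_idx), 3))
    v_mean = np.empty(n_steps + 1)
    u_p_tr = np.zeros(n_steps + 1)
    u_e_tr = np.zeros(n_steps + 1)
    raster: list = []

    u_e = 0.0
    k_circ = circuit.decay_rate_ms
    tau_ct = circuit.tau_ct_ms
    tidx = np.asarray(tracked_idx, dtype=int)

    def drift(Y, ue_val):
        V, h, r = Y[:, 0], Y[:, 1], Y[:, 2]
        dV, dh, dr = _rhs([V, h, r], params)
        dV = dV + (cfg.sigma * (V.mean() - V) + ue_val * scale) / params.C
        return np.stack([dV, dh, dr], axis=1)

    def probe_at(step):
        """(u_p, du_p) applied at integration step index ``step``."""
        if stimulus_source == "pulsatile":
            return up_sched[step], dup_sched[step]
        if stimulus_source == "event" and ctrl.playing:
            j = ctrl.play_idx
            if j < stim_len:
                return stim_up[j], stim_dup[j]
        return 0.0, 0.0

    v_mean[0] = X[:, 0].mean()
    rec_i = 0
    rec_t[0] = 0.0
    rec_V[0] = X[:, 0]
    rec_tracked[0] = X[tidx]

    for n in range(n_steps):
        t = n * dt
        up0, dup0 = probe_at(n)
        up1, dup1 = probe_at(n + 1) if stimulus_source == "pulsatile" else (up0, dup0)
        u_p_tr[n] = up0

        dW = sq_noise * rng.standard_normal(cfg.N)
        # Heun predictor-corrector; circuit advanced in the same two stages
        F1 = drift(X, u_e)
        due1 = dup0 + up0 / tau_ct - k_circ * u_e
        Xp = X.copy()
        Xp += dt * F1
        Xp[:, 0] += dW
        ue_p = u_e + dt * due1
        F2 = drift(Xp, ue_p)
        due2 = dup1 + up1 / tau_ct - k_circ * ue_p
        Xn = X + 0.5 * dt * (F1 + F2)
        Xn[:, 0] += dW
        u_e = u_e + 0.5 * dt * (due1 + due2)

        crossed = (X[:, 0] < SPIKE_THRESHOLD_MV) & (Xn[:, 0] >= SPIKE_THRESHOLD_MV)
        if crossed.any():
            for i in np.nonzero(crossed)[0]:
                frac = (SPIKE_THRESHOLD_MV - X[i, 0]) / (Xn[i, 0] - X[i, 0])
                raster.append((int(i), t + frac * dt))
        X = Xn
        if not np.all(np.isfinite(X)):
            raise RuntimeError(f"non-finite network state at t={t + dt:.3f} ms")

        v_mean[n + 1] = X[:, 0].mean()
        u_e_tr[n + 1] = u_e

        # controller operates on the sampled mean voltage
        if stimulus_source == "event":
            if ctrl.playing:
                ctrl.play_idx += 1
                if ctrl.play_idx >= stim_len:
                    ctrl.playing = False
                    ctrl.watch_deadline = (n + 1) * dt + lockout
                    ctrl.events.append(("stim_end", (n + 1) * dt))
            controller_step(ctrl, (n + 1) * dt, v_mean[n + 1], v_mean[n], stim_len, lockout)

        if (n + 1) % cfg.record_every == 0:
            rec_i += 1
            rec_t[rec_i] = (n + 1) * dt
            rec_V[rec_i] = X[:, 0]
            rec_tracked[rec_i] = X[tidx]

    u_p_tr[n_steps] = probe_at(n_steps)[0] if stimulus_source == "pulsatile" else u_p_tr[n_steps - 1]
    return PopulationTrace(
        t=rec_t[: rec_i + 1],
        V=rec_V[: rec_i + 1],
        v_mean=v_mean,
        t_full=np.arange(n_steps + 1) * dt,
        u_p=u_p_tr,
        u_e=u_e_tr,
        raster=raster,
        tracked=rec_tracked[: rec_i + 1],
        tracked_idx=tuple(tracked_idx),
        events=ctrl.events,
        config=cfg,
    )
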