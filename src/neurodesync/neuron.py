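"""Reduced conductance-based thalamic neuron model.

A three-variable (V, h, r) periodically spiking thalamocortical relay cell:
leak, sodium, potassium and low-threshold calcium (T-type) currents, with the
fast sodium activation slaved to its steady state and the potassium gate tied
to the sodium inactivation gate h.  With the default baseline current
I_SM = 5 uA/cm^2 the cell fires tonically with a period close to 8.4 ms.

Units: time in ms, voltage in mV, currents in uA/cm^2, capacitance in
uF/cm^2, conductances in mS/cm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "NeuronState",
    "NeuronParams",
    "membrane_current",
    "vector_field",
    "jacobian",
    "simulate_single",
    "SPIKE_THRESHOLD_MV",
]

#: Spike definition: upward crossing of this membrane voltage (mV).  Chosen
#: well above the controller thresholds (-45/-40 mV) and below the spike peak.
SPIKE_THRESHOLD_MV = -20.0


@dataclass(frozen=True)
class NeuronState:
    """Membrane state: voltage (mV) and the two slow gating variables."""

    V: float
    h: float
    r: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.h, self.r], dtype=float)

    @staticmethod
    def from_array(x: Sequence[float]) -> "NeuronState":
        return NeuronState(float(x[0]), float(x[1]), float(x[2]))


@dataclass(frozen=True)
class NeuronParams:
    """Constants of the reduced thalamic model.

    The defaults reproduce tonic firing with period T = 8.395 ms at
    ``I_SM = 5`` (the calibration anchor for the transcription of the
    current and gating functions).
    """

    C: float = 1.0        # membrane capacitance, uF/cm^2
    I_SM: float = 5.0     # baseline (somatomotor) current, uA/cm^2
    g_L: float = 0.05     # leak conductance, mS/cm^2
    E_L: float = -70.0
    g_Na: float = 3.0
    E_Na: float = 50.0
    g_K: float = 5.0
    E_K: float = -90.0
    g_T: float = 5.0
    E_T: float = 0.0

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError("membrane capacitance C must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


def export_trajectory(prefix, t, X, spikes) -> None:
    """Write a simulated trajectory as ``<prefix>.csv`` (columns t, V, h, r)
    and the spike times as ``<prefix>_spikes.json``."""
    import json

    import pandas as pd

    pd.DataFrame({"t": t, "V": X[:, 0], "h": X[:, 1], "r": X[:, 2]}).to_csv(
        f"{prefix}.csv", index=False
    )
    with open(f"{prefix}_spikes.json", "w") as fh:
        json.dump([float(s) for s in np.asarray(spikes)], fh)


# -- gating steady states and time constants ---------------------------------
# np.exp keeps these complex-safe so the Jacobian can be obtained by
# complex-step differentiation.

def m_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 37.0) / 7.0))


def h_inf(V):
    return 1.0 / (1.0 + np.exp((V + 41.0) / 4.0))


def r_inf(V):
    return 1.0 / (1.0 + np.exp((V + 84.0) / 4.0))


def p_inf(V):
    return 1.0 / (1.0 + np.exp(-(V + 60.0) / 6.2))


def tau_h(V):
    a_h = 0.128 * np.exp(-(V + 46.0) / 18.0)
    b_h = 4.0 / (1.0 + np.exp(-(V + 23.0) / 5.0))
    return 1.0 / (a_h + b_h)


def tau_r(V):
    return 28.0 + np.exp(-(V + 25.0) / 10.5)


def _currents(V, h, r, p: NeuronParams):
    I_L = p.g_L * (V - p.E_L)
    I_Na = p.g_Na * m_inf(V) ** 3 * h * (V - p.E_Na)
    I_K = p.g_K * (0.75 * (1.0 - h)) ** 4 * (V - p.E_K)
    I_T = p.g_T * p_inf(V) ** 2 * r * (V - p.E_T)
    return I_L, I_Na, I_K, I_T


def membrane_current(state: NeuronState | Sequence[float], params: NeuronParams) -> float:
    """Total intrinsic membrane current I_m (uA/cm^2).

    ``I_m = -I_L - I_Na - I_K - I_T + I_SM``: the ionic currents are
    subtracted and the baseline current added, so ``dV/dt = (I_m + i_app)/C``.
    """
    x = state.as_array() if isinstance(state, NeuronState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite neuron state: {x}")
    V, h, r = x
    I_L, I_Na, I_K, I_T = _currents(V, h, r, params)
    return float(-I_L - I_Na - I_K - I_T + params.I_SM)


def _rhs(x, params: NeuronParams, i_applied=0.0):
    """Vector field on a raw (V, h, r) array; complex-safe for x."""
    V, h, r = x[0], x[1], x[2]
    I_L, I_Na, I_K, I_T = _currents(V, h, r, params)
    I_m = -I_L - I_Na - I_K - I_T + params.I_SM
    dV = (I_m + i_applied) / params.C
    dh = (h_inf(V) - h) / tau_h(V)
    dr = (r_inf(V) - r) / tau_r(V)
    return np.array([dV, dh, dr])


def vector_field(
    state: NeuronState | Sequence[float],
    params: NeuronParams,
    i_applied: float = 0.0,
) -> np.ndarray:
    """Time derivative (dV/dt, dh/dt, dr/dt) with applied current ``i_applied``.

    The gating variables relax to their voltage-dependent steady states with
    time constants ``tau_h(V)`` and ``tau_r(V)``.
    """
    x = state.as_array() if isinstance(state, NeuronState) else np.asarray(state, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"non-finite neuron state: {x}")
    V = x[0]
    th, tr = tau_h(V), tau_r(V)
    if th <= 0 or tr <= 0:
        raise ZeroDivisionError(f"non-positive gating time constant at V={V} mV")
    return _rhs(x, params, i_applied)


def jacobian(x: Sequence[float], params: NeuronParams, i_applied: float = 0.0) -> np.ndarray:
    """3x3 Jacobian of the vector field by complex-step differentiation."""
    x = np.asarray(x, dtype=float)
    J = np.empty((3, 3))
    hstep = 1e-20
    for j in range(3):
        xc = x.astype(complex)
        xc[j] += 1j * hstep
        J[:, j] = _rhs(xc, params, i_applied).imag / hstep
    return J


def _spike_times_from_samples(t: np.ndarray, V: np.ndarray, threshold: float = SPIKE_THRESHOLD_MV) -> np.ndarray:
    """Upward threshold crossings located by linear interpolation."""
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return np.empty(0)
    frac = (threshold - V[idx]) / (V[idx + 1] - V[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def simulate_single(
    params: NeuronParams,
    applied_current: Callable[[float], float] | None = None,
    t_span: tuple[float, float] = (0.0, 200.0),
    x0: Sequence[float] | NeuronState | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_samples: int | None = None,
    method: str = "LSODA",
):
    """Integrate a single deterministic neuron and detect spikes.

    Parameters
    ----------
    applied_current : callable t -> uA/cm^2, optional
        External current added to the voltage equation (zero if omitted).
    t_span : (t0, t1)
        Integration window in ms.
    x0 : initial state; a sub-threshold resting-like state if omitted.
    n_samples : number of uniform output samples (default: 10 per ms).

    Returns
    -------
    (t, X, spike_times)
        Uniform sample times, an ``(n, 3)`` trajectory array, and spike times
        (upward crossings of ``SPIKE_THRESHOLD_MV``, linearly interpolated).
    """
    if applied_current is None:
        applied_current = lambda t: 0.0
    if x0 is None:
        x0 = np.array([-65.0, h_inf(-65.0), r_inf(-65.0)])
    elif isinstance(x0, NeuronState):
        x0 = x0.as_array()
    else:
        x0 = np.asarray(x0, dtype=float)
    t0, t1 = map(float, t_span)
    if not np.isfinite([t0, t1]).all():
        raise ValueError("t_span must be finite")
    if n_samples is None:
        n_samples = max(2, int(round((t1 - t0) * 10)) + 1)
    t_eval = np.linspace(t0, t1, n_samples)

    sol = solve_ivp(
        lambda t, x: _rhs(x, params, applied_current(t)),
        (t0, t1),
        x0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed at t={sol.t[-1] if sol.t.size else t0}: {sol.message}")
    spikes = _spike_times_from_samples(sol.t, sol.y[0])
    return sol.t, sol.y.T, spikes
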