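"""Probe-electrolyte interface: circuit, field geometry and input scalings.

The stimulation probe couples to the tissue through a double-layer
capacitance C_dl (non-damaging capacitive charge transfer), a charge-transfer
resistance R_ct (Faradaic, potentially damaging), and a spreading resistance
R_s of the extracellular medium.  Kirchhoff's current law gives a first-order
linear ODE for the field-side voltage V_e driven by the probe voltage V_p:

    dV_e/dt = dV_p/dt + (V_p - V_e)/(C_dl R_ct) - V_e/(C_dl R_s).

The extracellular potential of a spherical probe obeys the Laplace equation
and decays as 1/r; the effective input to a neuron at distance d is
proportional to the second spatial derivative of that potential along the
axon direction (the activating function), F(d) = a/d^3 per volt at the probe.

All control-level quantities are carried in "u-units": u_e = -F(d) V_e /
(R_i C) and u_p = -F(d) V_p / (R_i C) are fixed positive rescalings of the
voltages, so the circuit ODE is identical in u-units and every downstream
result is independent of the (unknown) intra-axonal resistance R_i.

Time is in ms internally: with the default constants C_dl*R_s = 14.5 ms and
C_dl*R_ct = 1e5 ms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "CircuitParams",
    "FieldGeometry",
    "StimulusWaveform",
    "probe_potential",
    "effective_strength",
    "simulate_circuit",
    "transfer_gain",
    "to_effective_input",
    "from_effective_input",
]

_S_TO_MS = 1e3


@dataclass(frozen=True)
class CircuitParams:
    """Electrode circuit constants (SI units as given; converted to ms internally)."""

    C_dl: float = 5e-4   # double-layer capacitance, F
    R_ct: float = 2e5    # charge-transfer resistance, Ohm
    R_s: float = 29.0    # spreading resistance, Ohm

    def __post_init__(self) -> None:
        if min(self.C_dl, self.R_ct, self.R_s) <= 0:
            raise ValueError("circuit constants must be strictly positive")

    @property
    def tau_ct_ms(self) -> float:
        """C_dl * R_ct in ms."""
        return self.C_dl * self.R_ct * _S_TO_MS

    @property
    def tau_s_ms(self) -> float:
        """C_dl * R_s in ms."""
        return self.C_dl * self.R_s * _S_TO_MS

    @property
    def decay_rate_ms(self) -> float:
        """Relaxation rate k = 1/(C_dl R_ct) + 1/(C_dl R_s) in 1/ms."""
        return 1.0 / self.tau_ct_ms + 1.0 / self.tau_s_ms

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class FieldGeometry:
    """Spherical-probe geometry and the scalings tying volts to u-units."""

    probe_radius: float = 0.5     # mm
    distance: float = 1.0         # mm, neuron distance from probe center
    R_i: float = 1.0              # effective intra-axonal resistance (model units)
    C: float = 1.0                # membrane capacitance, uF/cm^2

    def __post_init__(self) -> None:
        if self.distance <= self.probe_radius:
            raise ValueError("neuron distance must exceed the probe radius")

    @property
    def F(self) -> float:
        return effective_strength(self.probe_radius, self.distance)


def probe_potential(a: float, V_e: float, r) -> np.ndarray | float:
    """Extracellular potential of a sphere of radius ``a`` (mm) held at ``V_e``.

    Laplace solution outside a conducting sphere in a uniform medium:
    V(r) = V_e * a / r, matching the boundary at r = a and vanishing at
    infinity.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < a):
        raise ValueError("field point inside the probe (r < a)")
    out = V_e * a / r_arr
    return out if out.shape else float(out)


def effective_strength(a: float, d) -> np.ndarray | float:
    """Activating-function strength F(d) = d2V/dx2 at distance ``d`` for V_e = -1 V.

    Along the direction x perpendicular to the probe-neuron line the potential
    is V(x) = -a/sqrt(d^2+x^2); its second x-derivative at x = 0 is a/d^3
    (V/mm^2), positive and strictly decreasing in d.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr <= a):
        raise ValueError("neuron distance must exceed the probe radius (d > a)")
    out = a / d_arr**3
    return out if out.shape else float(out)


@dataclass
class StimulusWaveform:
    """A sampled stimulus: probe drive u_p and circuit response u_e on a shared
    uniform time grid (ms), in u-units."""

    t: np.ndarray
    u_p: np.ndarray
    u_e: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u_p = np.asarray(self.u_p, dtype=float)
        self.u_e = np.asarray(self.u_e, dtype=float)
        if not (self.t.shape == self.u_p.shape == self.u_e.shape):
            raise ValueError("t, u_p, u_e must share one grid")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def to_csv(self, path, circuit: CircuitParams | None = None, geometry: FieldGeometry | None = None) -> None:
        pd.DataFrame({"t_ms": self.t, "u_p": self.u_p, "u_e": self.u_e}).to_csv(path, index=False)
        if circuit is not None or geometry is not None:
            sidecar = {}
            if circuit is not None:
                sidecar["circuit"] = circuit.to_dict()
            if geometry is not None:
                sidecar["geometry"] = asdict(geometry)
            with open(str(path) + ".json", "w") as fh:
                json.dump(sidecar, fh, indent=1)

    @staticmethod
    def from_csv(path) -> "StimulusWaveform":
        df = pd.read_csv(path)
        return StimulusWaveform(df["t_ms"].to_numpy(), df["u_p"].to_numpy(), df["u_e"].to_numpy())


def simulate_circuit(
    t: np.ndarray,
    u_p: np.ndarray,
    params: CircuitParams | None = None,
    u_e0: float = 0.0,
) -> StimulusWaveform:
    """Drive the electrode circuit with a sampled probe waveform.

    The probe input is taken piecewise linear between samples, which makes
    the linear ODE exactly integrable on each step (exponential-integrator
    update with phi-functions); there is no time-discretization error beyond
    the piecewise-linear representation of u_p.
    """
    if params is None:
        params = CircuitParams()
    t = np.asarray(t, dtype=float)
    u_p = np.asarray(u_p, dtype=float)
    if t.shape != u_p.shape or t.ndim != 1 or t.size < 2:
        raise ValueError("t and u_p must be equal-length 1-D arrays")
    h = np.diff(t)
    if not np.allclose(h, h[0], rtol=1e-8):
        raise ValueError("time grid must be uniform")
    h = float(h[0])
    if h > params.tau_s_ms / 10.0:
        warnings.warn(
            f"grid step {h} ms is coarser than C_dl*R_s/10 = {params.tau_s_ms / 10.0} ms",
            stacklevel=2,
        )

    k = params.decay_rate_ms
    z = -k * h
    ez = np.exp(z)
    phi1 = -np.expm1(z) / (k * h)                 # (1 - e^{-kh})/(kh)
    phi2 = (ez - 1.0 - z) / (z * z)               # (e^{-kh} - 1 + kh)/(kh)^2

    slope = np.diff(u_p) / h
    # forcing g(tau) = du_p/dt + u_p/tau_ct is linear on each step: g0 + (dg) * tau/h
    g0 = slope + u_p[:-1] / params.tau_ct_ms
    dg = slope * h / params.tau_ct_ms

    from scipy.signal import lfilter

    b = h * phi1 * g0 + h * phi2 * dg
    u_e = np.empty_like(u_p)
    u_e[0] = u_e0
    # linear recurrence u[i+1] = ez*u[i] + b[i] as an IIR filter
    u_e[1:], _ = lfilter([1.0], [1.0, -ez], b, zi=np.array([ez * u_e0]))
    return StimulusWaveform(t=t, u_p=u_p.copy(), u_e=u_e)


def transfer_gain(frequency, params: CircuitParams | None = None):
    """Complex gain (V_p - V_e)/V_p of the interface at s = i*frequency (rad/ms).

    First-order low-pass form R_ct / (R_ct + R_s (R_ct C_dl s + 1)): fast
    probe transients reach the field with little loss across the double
    layer, slow ones leak through the Faradaic branch.
    """
    if params is None:
        params = CircuitParams()
    s = 1j * np.asarray(frequency, dtype=float)
    # R_ct C_dl in ms so that s in rad/ms is dimensionless in the product
    out = params.R_ct / (params.R_ct + params.R_s * (params.tau_ct_ms * s + 1.0))
    return out if out.shape else complex(out)


def to_effective_input(V, geom: FieldGeometry) -> np.ndarray | float:
    """Convert a voltage waveform (V) to u-units: u = -F(d) V / (R_i C)."""
    if geom.R_i == 0:
        raise ZeroDivisionError("R_i must be nonzero")
    out = -geom.F * np.asarray(V, dtype=float) / (geom.R_i * geom.C)
    return out if out.shape else float(out)


def from_effective_input(u, geom: FieldGeometry) -> np.ndarray | float:
    """Exact inverse of :func:`to_effective_input`."""
    if geom.R_i == 0:
        raise ZeroDivisionError("R_i must be nonzero")
    out = -np.asarray(u, dtype=float) * geom.R_i * geom.C / geom.F
    return out if out.shape else float(out)
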