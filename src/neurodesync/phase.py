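"""Limit cycle and phase response curve of the spiking neuron.

Phase reduction replaces the three-dimensional oscillator by a single phase
theta in [0, 2*pi), advancing at omega = 2*pi/T and anchored so that theta = 0
at the spike (upward crossing of the spike threshold).  The phase response
curve Z(theta) -- the voltage component of the adjoint solution normalized so
that <Z_full, xdot> = omega on the orbit -- converts an effective voltage-rate
input u_e(t) into a phase velocity perturbation:

    dtheta/dt = omega + Z(theta) * u_e(t).

All theta-indexed quantities (the orbit voltage f(theta), the PRC and their
derivatives) are stored as truncated Fourier series so they are smooth and
cheap to evaluate at arbitrary phase during boundary-value integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from neurodesync.neuron import (
    NeuronParams,
    SPIKE_THRESHOLD_MV,
    _rhs,
    jacobian,
    simulate_single,
)

__all__ = [
    "FourierSeries",
    "LimitCycle",
    "PRC",
    "find_limit_cycle",
    "compute_prc",
    "differentiate_periodic",
    "export_prc_csv",
    "import_prc_csv",
]


class FourierSeries:
    """Truncated real Fourier series of a 2*pi-periodic signal.

    Built from uniform samples by FFT; evaluation supports analytic
    differentiation to any order.
    """

    def __init__(self, samples: np.ndarray, n_harmonics: int = 64):
        samples = np.asarray(samples, dtype=float)
        n = samples.size
        K = min(n_harmonics, n // 2 - 1)
        c = np.fft.rfft(samples) / n
        self.a0 = c[0].real
        self.k = np.arange(1, K + 1)
        self.a = 2.0 * c[1 : K + 1].real   # cos coefficients
        self.b = -2.0 * c[1 : K + 1].imag  # sin coefficients
        self.n_harmonics = K

    def __call__(self, theta, deriv: int = 0):
        theta = np.asarray(theta, dtype=float)
        kt = np.multiply.outer(theta, self.k)
        ck, sk = np.cos(kt), np.sin(kt)
        kpow = self.k ** deriv if deriv else 1.0
        # derivative cycles cos -> -sin -> -cos -> sin
        if deriv % 4 == 0:
            val = ck @ (kpow * self.a) + sk @ (kpow * self.b)
        elif deriv % 4 == 1:
            val = -sk @ (kpow * self.a) + ck @ (kpow * self.b)
        elif deriv % 4 == 2:
            val = -ck @ (kpow * self.a) - sk @ (kpow * self.b)
        else:
            val = sk @ (kpow * self.a) - ck @ (kpow * self.b)
        if deriv == 0:
            val = val + self.a0
        return val if val.shape else float(val)


def differentiate_periodic(samples: np.ndarray, order: int = 1) -> np.ndarray:
    """Spectral derivative of a uniformly sampled 2*pi-periodic signal.

    Warns when the top quartile of retained modes carries more than half of
    the spectral energy, which indicates the signal is too rough for
    trustworthy spectral differentiation.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.size
    c = np.fft.rfft(samples)
    power = np.abs(c[1:]) ** 2
    if power.sum() > 0:
        top = power[3 * power.size // 4 :].sum()
        if top > 0.5 * power.sum():
            warnings.warn(
                ">50% of spectral energy in the top quartile of modes; "
                "spectral derivative may be unreliable",
                stacklevel=2,
            )
    k = np.arange(c.size)
    return np.fft.irfft(c * (1j * k) ** order, n=n)


@dataclass
class LimitCycle:
    """Stable periodic orbit parameterized by phase.

    Attributes
    ----------
    T : period (ms);  omega = 2*pi/T (rad/ms).
    theta : uniform phase grid on [0, 2*pi).
    states : (grid, 3) orbit samples (V, h, r); ``states[0]`` is the spike point.
    f, fp, fpp : on-orbit voltage map f(theta) (mV) and its theta-derivatives,
        evaluable at arbitrary phase.
    """

    T: float
    theta: np.ndarray
    states: np.ndarray
    _series: tuple[FourierSeries, FourierSeries, FourierSeries]

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.T

    def orbit(self, theta):
        """Interpolated orbit state(s) at arbitrary phase."""
        theta = np.asarray(theta, dtype=float)
        out = np.stack([s(theta, 0) for s in self._series], axis=-1)
        return out

    def f(self, theta):
        return self._series[0](theta, 0)

    def fp(self, theta):
        return self._series[0](theta, 1)

    def fpp(self, theta):
        return self._series[0](theta, 2)


@dataclass
class PRC:
    """Phase response curve Z(theta) (rad per mV of instantaneous voltage kick)
    with spectral derivatives, stored as a truncated Fourier series."""

    series: FourierSeries
    theta: np.ndarray
    samples: np.ndarray

    def Z(self, theta):
        return self.series(theta, 0)

    def Zp(self, theta):
        return self.series(theta, 1)

    def Zpp(self, theta):
        return self.series(theta, 2)


def find_limit_cycle(
    params: NeuronParams | None = None,
    grid_size: int = 512,
    settle_time: float = 1500.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    n_harmonics: int = 64,
) -> LimitCycle:
    """Locate the stable spiking orbit and parameterize it by phase.

    The model is integrated past its transient (the T-current gate relaxes
    with a ~28 ms time constant, so the transient is long compared to the
    period), the period is read off threshold-crossing events, and one final
    period starting at the spike point is resampled on a uniform phase grid.

    Raises ``RuntimeError`` if no spikes occur within the settling horizon.
    """
    if params is None:
        params = NeuronParams()

    def spike_event(t, x):
        return x[0] - SPIKE_THRESHOLD_MV

    spike_event.direction = 1.0

    x0 = np.array([-65.0, 0.1, 0.1])
    sol = solve_ivp(
        lambda t, x: _rhs(x, params),
        (0.0, settle_time),
        x0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        events=spike_event,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"settling integration failed: {sol.message}")
    ev_t = sol.t_events[0]
    ev_x = sol.y_events[0]
    if ev_t.size < 3:
        raise RuntimeError("model is not oscillating: fewer than 3 spikes in settling horizon")
    T = float(ev_t[-1] - ev_t[-2])
    x_spike = ev_x[-1]

    t_grid = np.arange(grid_size) * (T / grid_size)
    sol2 = solve_ivp(
        lambda t, x: _rhs(x, params),
        (0.0, T),
        x_spike,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        t_eval=t_grid,
    )
    if not sol2.success:
        raise RuntimeError(f"orbit sampling failed: {sol2.message}")
    states = sol2.y.T
    theta = 2.0 * np.pi * t_grid / T
    series = tuple(FourierSeries(states[:, i], n_harmonics) for i in range(3))
    return LimitCycle(T=T, theta=theta, states=states, _series=series)


def compute_prc(
    lc: LimitCycle,
    params: NeuronParams | None = None,
    n_harmonics: int = 64,
    max_periods: int = 40,
    conv_tol: float = 1e-8,
    rtol: float = 1e-10,
) -> PRC:
    """Phase response curve by the adjoint method.

    The adjoint equation ``zdot = -J(x(t))^T z`` is integrated backward in
    time along the orbit (backward integration is stable for a stable limit
    cycle), renormalizing once per period so that ``<z, xdot> = omega`` at the
    spike point, until successive periods agree to ``conv_tol`` in relative
    max-norm.  The voltage component sampled over one period is Z(theta).
    """
    if params is None:
        params = NeuronParams()
    T, omega = lc.T, lc.omega
    grid = lc.theta.size

    def orbit_state(t_back):
        # backward time s: physical time t = -s, phase = -omega*s mod 2*pi
        return lc.orbit(np.mod(-omega * t_back, 2.0 * np.pi))

    def rhs(s, z):
        J = jacobian(orbit_state(s), params)
        return J.T @ z

    xdot0 = _rhs(lc.states[0], params)
    # Seed with the left unit-multiplier eigenvector of the monodromy matrix:
    # the slow Floquet mode (the T-current gate relaxes over ~28 ms >> T)
    # would otherwise take ~100 renormalized periods to die out.
    def fund_rhs(t, m):
        J = jacobian(lc.orbit(np.mod(omega * t, 2.0 * np.pi)), params)
        return (J @ m.reshape(3, 3)).ravel()

    solM = solve_ivp(fund_rhs, (0.0, T), np.eye(3).ravel(), method="LSODA", rtol=rtol, atol=1e-12)
    if not solM.success:
        raise RuntimeError(f"monodromy integration failed: {solM.message}")
    M = solM.y[:, -1].reshape(3, 3)
    evals, evecs = np.linalg.eig(M.T)
    z = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
    z *= omega / float(z @ xdot0)

    prev = None
    for period in range(max_periods):
        sol = solve_ivp(rhs, (0.0, T), z, method="LSODA", rtol=rtol, atol=1e-12)
        if not sol.success:
            raise RuntimeError(f"adjoint integration failed: {sol.message}")
        z = sol.y[:, -1]
        z *= omega / float(z @ xdot0)
        if prev is not None and np.max(np.abs(z - prev)) < conv_tol * np.max(np.abs(z)):
            break
        prev = z.copy()
    else:
        raise RuntimeError("adjoint iteration did not converge to a periodic solution")

    # final pass: sample the periodic adjoint on the phase grid
    s_grid = np.arange(grid) * (T / grid)  # backward times; theta = -omega*s mod 2pi
    sol = solve_ivp(rhs, (0.0, T), z, method="LSODA", rtol=rtol, atol=1e-12, t_eval=s_grid)
    if not sol.success:
        raise RuntimeError(f"adjoint sampling failed: {sol.message}")
    # backward sample k sits at theta = (-omega*s_k) mod 2pi, i.e. grid index (grid-k) % grid
    Ztheta = np.empty((grid, 3))
    Ztheta[0] = sol.y[:, 0]
    Ztheta[1:] = sol.y[:, 1:][:, ::-1].T
    # enforce <z, xdot> = omega pointwise (exact for the true adjoint; this
    # projects out residual orbit-interpolation and solver error)
    dots = np.einsum("kj,kj->k", Ztheta, np.array([_rhs(s, params) for s in lc.states]))
    Ztheta *= (omega / dots)[:, None]
    samples = Ztheta[:, 0]
    series = FourierSeries(samples, n_harmonics)
    prc = PRC(series=series, theta=lc.theta.copy(), samples=samples)
    prc.full = Ztheta  # all three adjoint components, for the normalization identity
    return prc


def normalization_residual(prc: PRC, lc: LimitCycle, params: NeuronParams | None = None) -> np.ndarray:
    """Pointwise residual of <Z_full, xdot> = omega over the phase grid."""
    if params is None:
        params = NeuronParams()
    dots = np.array([float(prc.full[k] @ _rhs(lc.states[k], params)) for k in range(lc.theta.size)])
    return dots - lc.omega


def direct_prc(
    lc: LimitCycle,
    params: NeuronParams | None = None,
    phases: np.ndarray | None = None,
    kick: float = 0.01,
    horizon_periods: int = 12,
) -> tuple[np.ndarray, np.ndarray]:
    """PRC by direct perturbation: small voltage kicks, asymptotic phase shift.

    Independent of the adjoint computation; used as a cross-validation oracle.
    Returns (phases, Z_estimates) where the estimate is the asymptotic phase
    advance per mV of instantaneous voltage displacement.
    """
    if params is None:
        params = NeuronParams()
    if phases is None:
        phases = np.linspace(0, 2 * np.pi, 32, endpoint=False)
    T = lc.T
    horizon = horizon_periods * T
    est = np.empty(phases.size)
    for i, th in enumerate(phases):
        x = lc.orbit(th)
        t_ref = _time_to_late_spike(x, params, horizon)
        xk = x.copy()
        xk[0] += kick
        t_kick = _time_to_late_spike(xk, params, horizon)
        # earlier late-spike time => phase advance
        est[i] = (t_ref - t_kick) * lc.omega / kick
    return phases, est


def _time_to_late_spike(x0, params, horizon):
    _, _, spikes = simulate_single(
        params, t_span=(0.0, horizon), x0=x0, rtol=1e-10, atol=1e-12,
        n_samples=int(horizon * 40) + 1,
    )
    if spikes.size == 0:
        raise RuntimeError("no spikes in direct-PRC probe")
    return float(spikes[-1])


def export_prc_csv(path, lc: LimitCycle, prc: PRC) -> None:
    """Write theta, Z, Z', Z'', f, f', f'' on the phase grid as CSV."""
    th = lc.theta
    df = pd.DataFrame(
        {
            "theta": th,
            "Z": prc.Z(th),
            "Zp": prc.Zp(th),
            "Zpp": prc.Zpp(th),
            "f": lc.f(th),
            "fp": lc.fp(th),
            "fpp": lc.fpp(th),
        }
    )
    df.attrs["T"] = lc.T
    with open(path, "w") as fh:
        fh.write(f"# period_ms={lc.T!r}\n")
        df.to_csv(fh, index=False)


def import_prc_csv(path) -> tuple[LimitCycle, PRC]:
    """Rebuild (LimitCycle, PRC) surrogates from an exported CSV.

    Only the phase-indexed maps (f and Z families) are reconstructed; the
    state-space orbit columns h, r are not stored and the returned limit
    cycle carries the voltage map only.
    """
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# period_ms="):
            raise ValueError("missing period header in PRC CSV")
        T = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    theta = df["theta"].to_numpy()
    fvals = df["f"].to_numpy()
    fs = FourierSeries(fvals, 64)
    states = np.column_stack([fvals, np.zeros_like(fvals), np.zeros_like(fvals)])
    lc = LimitCycle(T=T, theta=theta, states=states, _series=(fs, FourierSeries(states[:, 1]), FourierSeries(states[:, 2])))
    prc = PRC(series=FourierSeries(df["Z"].to_numpy(), 64), theta=theta, samples=df["Z"].to_numpy())
    return lc, prc
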