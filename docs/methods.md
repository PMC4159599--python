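# Methods

`neurodesync` designs and evaluates energy-efficient extracellular stimuli
that *desynchronize* a population of periodically spiking model neurons, in
the spirit of closed-loop deep brain stimulation (DBS). This note documents
the models, the numerical choices, and the places where the design was
genuinely open.

## Neuron model

The single cell is a reduced three-variable thalamocortical relay neuron
(voltage `V`, sodium-inactivation gate `h`, T-current gate `r`):

    C dV/dt = -I_L - I_Na - I_K - I_T + I_SM + I_applied
    dh/dt   = (h_inf(V) - h)/tau_h(V)
    dr/dt   = (r_inf(V) - r)/tau_r(V)

with leak `I_L = g_L (V - E_L)`, sodium `I_Na = g_Na m_inf(V)^3 h (V -
E_Na)` (fast activation slaved to steady state), potassium `I_K = g_K
(0.75(1-h))^4 (V - E_K)` (gate tied to `1-h`), and low-threshold calcium
`I_T = g_T p_inf(V)^2 r (V - E_T)`.  Defaults (`g_L=0.05, E_L=-70, g_Na=3,
E_Na=50, g_K=5, E_K=-90, g_T=5, E_T=0`, `C=1 uF/cm^2`, `I_SM=5 uA/cm^2`)
produce tonic firing with period `T = 8.3956 ms`, the calibration anchor for
the transcription (printed reference: 8.395 ms). The T-current gate relaxes
over ~28 ms, so transients outlast many firing periods; limit-cycle
extraction discards 1.5 s before reading the period off threshold-crossing
events. A spike is an upward crossing of -20 mV, located by linear
interpolation.

Units throughout: ms, mV, uA/cm^2, uF/cm^2. Electrode circuit constants are
converted to ms internally (`C_dl R_s = 14.5 ms`, `C_dl R_ct = 1e5 ms`).

## Phase reduction

The stable orbit is parameterized by phase `theta in [0, 2*pi)`, anchored at
the spike, and the phase response curve `Z(theta)` is the voltage component
of the adjoint solution normalized by `<Z_full, xdot> = omega`. The adjoint
is seeded with the unit-multiplier left eigenvector of the monodromy matrix
(without this, the slow Floquet mode, multiplier ~0.83/period, would need
~100 renormalized backward periods to decay below 1e-8) and then iterated
backward with per-period renormalization until successive periods agree to
1e-8 in relative max-norm. The identity `<Z_full, xdot> = omega` is enforced
pointwise on the phase grid before smoothing; it is exact for the true
adjoint, so this only projects out interpolation and solver error.

All phase-indexed quantities (`f`, `Z` and their derivatives) are stored as
64-harmonic Fourier series of 512-point grids, making `Z'`, `Z''`, `f'`,
`f''` smooth and cheap during boundary-value integration. A direct
perturbation oracle (small voltage kicks, asymptotic spike-time shift)
agrees with the adjoint PRC to <2% and is part of the test suite.

For the default cell, `Z` has a single dominant positive lobe peaking near
`theta ~ 4.43`, and `sigma * mean(f'(theta) Z(theta)) = 0.04428` at
`sigma = 0.07` (printed reference: 0.0443): electrotonic coupling is net
synchronizing, contracting phase differences at ~0.044/ms.

## Electrode interface

The probe couples through a double-layer capacitance `C_dl` (capacitive,
non-damaging), a charge-transfer resistance `R_ct` (Faradaic, damaging) and
a spreading resistance `R_s`, giving the linear circuit ODE

    du_e/dt = du_p/dt + (u_p - u_e)/(C_dl R_ct) - u_e/(C_dl R_s).

All control-level computation is in "u-units" (`u = -F(d) V/(R_i C)`), fixed
positive rescalings of the probe/field voltages; every reported number is
independent of the unknown intra-axonal resistance `R_i`. The spherical
probe's extracellular potential is the closed-form `V_e a / r` Laplace
solution; the activating-function strength is `F(d) = a/d^3` per volt, so a
neuron at 2 mm receives 1/8 the input of one at 1 mm. Standalone circuit
simulation uses an exact exponential-integrator update (piecewise-linear
input, phi-function formulas), so the only discretization error is the
piecewise-linear representation of `u_p`; inside the stochastic network loop
the circuit state is advanced with the same fixed-step two-stage scheme as
the neurons.

## Stimulus design

The design cost over a stimulus window `t1 = 8.02 ms` (phase span ~6.0 rad,
deliberately less than one period so the stimulus ends before the next
spike) is

    G[u_p] = int_0^t1 [ u_e^2 + alpha (du_p/dt)^2 - beta Z'(theta) u_e
                        + gamma (u_p - u_e)^2 ] dt

with the circuit ODE and the phase equation `dtheta/dt = omega + Z(theta)
u_e` as constraints. `-beta Z' u_e` rewards a positive finite-time Lyapunov
exponent; `u_e^2` is injected energy; `gamma (u_p-u_e)^2` penalizes Faradaic
transfer; `alpha (du_p/dt)^2` regularizes the otherwise singular problem.
Defaults: `alpha=0.2, beta=50, gamma=8`.

Stationarity yields a six-dimensional Euler-Lagrange boundary-value problem
in `(u_p, du_p/dt, theta, u_e, lambda1, lambda2)`. Two boundary sets are
implemented:

* **transversal** (default): `u_p(0) = theta(0) = u_e(0) = 0`,
  `u_p(t1) = u_e(t1) = 0`, `lambda2(t1) = 0` (the natural condition for the
  free terminal phase; the initial probe slew is free).
* **printed**: the initial slew `du_p/dt(0) = 0` is imposed instead and
  `lambda2(t1)` is left free.

These are not equivalent. Imposing the initial slew *and* leaving the
terminal phase free over-determines the variational problem (seven boundary
conditions on a six-dimensional system): under the printed set the cost's
infimum is approached through a vanishing-cost boundary layer at `t = 0` and
is not attained, and the printed BVP's (unique, Newton-robust) solution is a
constrained stationary point that a direct adjoint-gradient minimization of
the same cost escapes (cost -6.2 vs -18.3 at `gamma=0`). Only under the
transversal set is the returned stimulus a genuine local minimum — the
perturbation spot check in the test suite (200 random smooth
circuit-consistent perturbations with fixed endpoints) passes for it and
fails for the printed set. The default is therefore the transversal set.

Two solvers are provided. Shooting on the two initial multipliers with the
nested double-bisection bracket search is exposed (`shoot`,
`double_bisection`) and works with blow-up-direction sentinels — generic
multiplier guesses blow up in finite time, and the escape direction carries
the residual sign — but the multiplier dynamics amplify initial
perturbations by ~1e12 over the window, so shooting alone cannot satisfy
the terminal conditions to better than ~1e-4 relative in double precision.
`design_stimulus` therefore solves by collocation (damped-Newton,
tolerance 1e-8, boundary conditions satisfied to machine precision), seeded
from a smooth default guess, a shooting root, or a previous design for
weight continuation. Candidate solutions with `max|u_e| > 50` u-units are
rejected as invalidating the phase reduction.

Designed exponents over the Faradaic-weight sweep (`gamma = 0, 8, 32, 64,
120, 180`, evaluated as the Eq.-(8)-style path average `int Z'(theta(s))
u(s) ds / T` with `theta` integrated under the stimulus, not the
`theta ~ omega t` shortcut):

    Lambda(T) = 0.132, 0.109, 0.074, 0.055, 0.039, 0.031    (this package)
    reference = 0.097, 0.077, 0.054, 0.040, 0.028, 0.021    (printed)

The ladder is strictly decreasing and matches the printed ladder in *ratio*
to ~2% at every `gamma`, but is uniformly ~1.37x larger. The printed
boundary set gives a ladder uniformly ~2x *smaller* (0.049 at `gamma=0`).
No evaluation convention tested (driven phase vs `omega t`, horizon `T` vs
`t1`, probe vs field input) removes the scale factor consistently, while
the period, the PRC peak location, the coupling-only contraction rate
0.0443 and the pulsatile energy/Faradaic metrics all reproduce to <1%; the
residual scale factor on the designed-stimulus exponents is a known,
documented discrepancy. Two full conductance-model neurons driven by a
designed stimulus separate at the rate the phase model predicts to within
~9%, so the reported exponents are correct for the stimuli this package
produces.

Including electrotonic coupling in the design (extra
`beta sigma (f'' Z + f' Z')` term in the `lambda2` equation) changes the
`gamma=8` stimulus by only 3.8% in max-norm — exploiting the phase-model
dynamics is far cheaper than fighting coupling directly.

## Finite-time Lyapunov exponents

For two neurons receiving the same input, `Lambda(tau) = (1/tau) int
Z'(theta(s)) u(s) ds` along the driven phase trajectory; positive means
desynchronizing. With all-to-all electrotonic coupling the coupled exponent
subtracts `sigma f'(theta) Z(theta)` (symmetric-ensemble approximation; the
exact-ensemble variant with the `(sigma/N) sum_i (f(theta_i) - f(theta))`
term is also implemented). At `sigma = 0` all variants coincide to machine
precision; a two-trajectory variational oracle validates the path-average
form to <1% across random smooth inputs.

The simulation-based estimate freezes each tracked neuron's state at every
recorded sample and simulates it forward input-free (batched fixed-step
RK4, horizon 2T) to its next spike: `theta = 2*pi*(1 - t_next/T)`. The
exponent is the least-squares slope of `log|theta2 - theta1|` from stimulus
onset until the difference first exceeds 1 rad (beyond which the
linearization fails) or falls below a floor (default 1e-4 rad, above the
phase-inference quantization noise); a fit with R^2 < 0.9 is flagged
non-exponential.

## Population simulation

N neurons (default 100) with mean-field voltage-difference coupling
`sigma (Vbar - V_i)`, i.i.d. Gaussian white noise of variance `2D = 0.7`
in each voltage equation, and the shared circuit field input scaled per
neuron by `1/d_i^3`. Integration is fixed-step stochastic Heun (dt = 0.01
ms): an Euler-Maruyama predictor and trapezoidal drift corrector sharing
one Wiener increment per step. With `D = 0` it reproduces adaptive-solver
spike times to <1e-2 ms over ten periods; short-horizon voltage variance
scales linearly in `2D`.

Near-synchronous initial conditions sample the orbit at phases `N(0,
0.1 rad)` (the reference text does not state its initialization; 0.1 rad is
a tightly synchronized, pathological-synchrony-like state). The synthetic
fixtures (initial phases, probe distances, unit pulse trains) are seeded
and generated at run time; no external data exists anywhere in the
pipeline. What passing tests show is therefore internal consistency of the
model chain, not agreement with any biological recording: real thalamic
populations are heterogeneous in parameters (not only in probe distance),
synaptically as well as electrotonically coupled, and observed through
noisy field potentials rather than exact mean voltage.

The event-based controller is two-state. Active: every fresh upward
crossing of `Vbar = -45 mV` followed by a falling sample triggers the
stimulus (a playback in progress is restarted; at most one stimulus plays
at a time). If no crossing occurs within 1.5 T after a stimulus ends, the
controller goes inactive; it re-arms when `Vbar` registers above -40 mV.
For a synchronized population this locks stimulation to the early phase
(~0.2-0.35 rad after the population spike) once per period; after
desynchronization flattens `Vbar`, stimulation stops until the population
re-synchronizes (in the noisy runs, roughly every 100 ms). The trigger
phase matters: the designed stimuli assume onset at `theta = 0`, and their
exponent decays quickly with onset offset (sign flip by ~0.7 rad), which is
why the closed-loop fitted exponents are substantially smaller than the
open-loop `Lambda(T)` of the same stimuli.

The pulsatile baseline is a charge-balanced biphasic train (0.2 ms per
phase, 4 ms period, amplitude 98 u-units, anodic-first by default — the
sign order is unstated in the reference and energy/charge metrics are
order-invariant). The sampled train carries an explicit rising edge at
`t = 0`; losing that edge silently discards the capacitive step and leaves
a large DC transient in `u_e` that corrupts both metrics. Over 300 ms the
train injects `int u_e^2 dt ~ 2.9e5` units with Faradaic measure
`int |u_p - u_e|/R_ct dt ~ 1.8e-4`, versus a few hundred units of energy
for the event-based designed stimulus — the three-orders-of-magnitude
energy saving that motivates the method.

## Problem sizes and tolerances

Phase grid 512 (tests cross-check 256); adaptive integrations at rtol
1e-8..1e-10; collocation tolerance 1e-8; network dt 0.01 ms; noise-free
exponent runs 200 ms with N=100; stochastic energy runs 10 seeds x 300 ms.
The experiment layer (`neurodesync.workbench`) memoizes the phase model and
designs per process, and every experiment is deterministic given its seed.

## Known limitations

* The designed-exponent scale disagreement with the printed reference
  ladder (ratios match to ~2%, absolute values ~1.37x) is unresolved; both
  boundary-condition variants are shipped so the comparison is
  reproducible.
* The double-layer is a true capacitance (`n = 1`); constant-phase-element
  behavior, non-spherical electrodes and reaction kinetics beyond the
  linear `R_ct` approximation are out of scope.
* Synaptic coupling, bursting regimes and multi-compartment axon models are
  not implemented; the vector-field interface accepts alternative models
  but only the reduced thalamic cell ships.
* Phase inference is ballistic and noise-free by construction; exponents
  are not estimated from stochastic trajectories.
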