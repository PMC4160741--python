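"""Model dynamics: active parameters, stimulation protocols and simulations.

The reduced motoneuron couples a Morris-Lecar-style spiking soma (fast
sodium-like inward current with instantaneous activation ``m_S``, delayed
rectifier gate ``n_S``) to a dendrite carrying an L-type calcium persistent
inward current (PIC, gate ``m_D``) and a potassium current (gate ``n_D``).
Two protocols are provided:

* :func:`simulate_ramp` — a triangular somatic current clamp, the standard
  protocol used to classify firing types from frequency-current hysteresis;
* :func:`simulate_vclamp` — a triangular somatic voltage clamp used to
  characterise the PIC measured at the soma.  The leak reference is a
  companion run with the PIC conductance removed (``g_ca = 0``), so the PIC
  current is exactly zero when the PIC is blocked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels
from .cable_core import CableParameters, SystemProperties

__all__ = [
    "ActiveParameters",
    "RampProtocol",
    "VClampProtocol",
    "StateTrajectory",
    "derivatives",
    "find_rest",
    "simulate_ramp",
    "simulate_vclamp",
]

#: Tolerances for the adaptive Dormand-Prince 5(4) cross-check method.
RTOL = 1e-8
ATOL = 1e-10
#: Default output sampling step, fine enough to resolve spike upstrokes.
DT_OUT = 0.1
#: Default internal step of the split exponential integrator.
H_SPLIT = 0.05


@dataclass(frozen=True)
class ActiveParameters:
    """Active-channel constants of the reduced model (all dimensionless).

    The activation curves are ``x_inf(V) = 0.5 (1 + tanh((V - V1)/V2))`` and
    the gate time constants ``tau(V) = 1/cosh((V - a)/b)`` with the printed
    constants; ``phi`` is the shared rate factor of the three gates.  The
    dendritic PIC activation is governed by ``(g_ca, v1d, v2d)`` — the triple
    that monoaminergic neuromodulation scales.  ``tie_tau_to_activation``
    makes the dendritic time-constant constants follow (v1d, v2d) instead of
    the fixed printed pair (0.07, 0.1); it is off by default.
    """

    g_na: float = 11.0
    g_ks: float = 14.0
    g_ca: float = 0.89
    g_kd: float = 0.44
    e_na: float = 1.0
    e_k: float = -0.7
    e_ca: float = 1.0
    e_leak: float = -0.5
    v1d: float = 0.07
    v2d: float = 0.1
    phi: float = 0.2
    v1s: float = -0.01
    v2s: float = 0.15
    tau_md_v1: float = 0.07
    tau_md_v2: float = 0.1
    tie_tau_to_activation: bool = False

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_ks, self.g_ca, self.g_kd) < 0:
            raise ValueError("conductances must be nonnegative")
        if self.v2d <= 0:
            raise ValueError("v2d must be positive")
        if not (self.e_k < self.e_leak < self.e_na):
            raise ValueError("require e_k < e_leak < e_na")

    def with_gca(self, g_ca: float) -> "ActiveParameters":
        return replace(self, g_ca=g_ca)


@dataclass(frozen=True)
class RampProtocol:
    """Triangular somatic current clamp.

    ``peak`` is reached at ``pre_relax + duration/2``; the stimulus returns to
    zero at ``pre_relax + duration`` (symmetric rise and fall).
    """

    peak: float = 2.5
    duration: float = 3000.0
    pre_relax: float = 500.0

    def __post_init__(self) -> None:
        if self.peak < 0 or self.duration <= 0 or self.pre_relax < 0:
            raise ValueError("invalid ramp protocol")

    @property
    def t_peak(self) -> float:
        return self.pre_relax + self.duration / 2.0

    @property
    def t_end(self) -> float:
        return self.pre_relax + self.duration

    def current(self, t):
        """Stimulus value(s) at time(s) ``t`` (vectorised)."""
        t = np.asarray(t, float)
        tt = t - self.pre_relax
        half = self.duration / 2.0
        up = self.peak * tt / half
        down = self.peak * (self.duration - tt) / half
        out = np.where(tt < half, up, down)
        out = np.where((tt <= 0) | (tt >= self.duration), 0.0, out)
        return out if out.ndim else float(out)

    def ascending_time_at(self, current: float) -> float:
        """Time on the rising limb at which the stimulus equals ``current``."""
        return self.pre_relax + (current / self.peak) * self.duration / 2.0

    def descending_time_at(self, current: float) -> float:
        """Time on the falling limb at which the stimulus equals ``current``."""
        return self.t_end - (current / self.peak) * self.duration / 2.0


@dataclass(frozen=True)
class VClampProtocol:
    """Triangular somatic voltage clamp from ``v_base`` to ``v_peak`` and back."""

    v_base: float = -0.5
    v_peak: float = 0.3
    duration: float = 3000.0
    pre_relax: float = 500.0

    def __post_init__(self) -> None:
        if self.v_peak <= self.v_base:
            raise ValueError("v_peak must exceed v_base")

    @property
    def t_end(self) -> float:
        return self.pre_relax + self.duration

    def command(self, t):
        t = np.asarray(t, float)
        tt = t - self.pre_relax
        half = self.duration / 2.0
        span = self.v_peak - self.v_base
        up = self.v_base + span * tt / half
        down = self.v_base + span * (self.duration - tt) / half
        out = np.where(tt < half, up, down)
        out = np.where((tt <= 0) | (tt >= self.duration), self.v_base, out)
        return out if out.ndim else float(out)


@dataclass
class StateTrajectory:
    """Sampled solution of one protocol run.

    ``i_s`` is the applied stimulus under current clamp or the measured clamp
    current under voltage clamp.  ``valid`` is False when the integrator
    failed; such trajectories are treated as nonphysiological downstream.
    """

    t: np.ndarray
    v_s: np.ndarray
    v_d: np.ndarray
    n_s: np.ndarray
    m_d: np.ndarray
    n_d: np.ndarray
    i_s: np.ndarray
    valid: bool = True


def _pack(cable: CableParameters, sys: SystemProperties, active: ActiveParameters) -> np.ndarray:
    a = active
    tmd1, tmd2 = (
        (a.v1d, a.v2d) if a.tie_tau_to_activation else (a.tau_md_v1, a.tau_md_v2)
    )
    return np.array(
        [
            cable.g_ms, cable.g_md, cable.g_c, cable.c_ms, cable.c_md,
            sys.p,
            a.g_na, a.g_ks, a.g_ca, a.g_kd,
            a.e_na, a.e_k, a.e_ca, a.e_leak,
            a.v1d, a.v2d, a.phi,
            a.v1s, a.v2s,
            tmd1, tmd2,
        ]
    )


def gating_steady_state(v: float, active: ActiveParameters) -> tuple[float, float, float]:
    """Voltage-clamped steady-state values of (n_S, m_D, n_D) at potential ``v``."""
    n_s = 0.5 * (1.0 + math.tanh((v + 0.04) / 0.1))
    m_d = 0.5 * (1.0 + math.tanh((v - active.v1d) / active.v2d))
    n_d = 0.5 * (1.0 + math.tanh(v / 0.1))
    return n_s, m_d, n_d


def derivatives(
    state,
    t: float,
    cable: CableParameters,
    sys: SystemProperties,
    active: ActiveParameters,
    stimulus_value: float = 0.0,
) -> np.ndarray:
    """Reference right-hand side of the five-state model (plain NumPy).

    ``state`` is ``(v_s, v_d, n_s, m_d, n_d)``.  This function exists as the
    readable specification of the equations; simulations use the compiled
    kernel, which is cross-checked against this implementation in the tests.
    """
    P = _pack(cable, sys, active)
    dy = np.empty(5)
    _kernels.rhs_cc.py_func(t, np.asarray(state, float), P, stimulus_value, dy)
    return dy


def _rest_initial_state(active: ActiveParameters) -> np.ndarray:
    v0 = active.e_leak
    n_s, m_d, n_d = gating_steady_state(v0, active)
    return np.array([v0, v0, n_s, m_d, n_d])


def find_rest(
    cable: CableParameters,
    sys: SystemProperties,
    active: ActiveParameters,
    settle_time: float = 500.0,
    rate_tol: float = 1e-6,
) -> tuple[np.ndarray, bool]:
    """Relax the model with zero stimulus and return (state, converged).

    Starting from ``(e_leak, e_leak)`` with gates at their steady states, the
    model is integrated for ``settle_time``; convergence requires the rate
    norm at the endpoint to fall below ``rate_tol``.  A non-convergent rest
    (e.g. spontaneous spiking or a self-sustaining plateau) is flagged, not
    raised.
    """
    if not cable.valid:
        raise ValueError("find_rest requires a valid cable")
    P = _pack(cable, sys, active)
    y0 = _rest_initial_state(active)
    _, Y, _, ok = _kernels.integrate_cc_split(
        P, y0, settle_time, DT_OUT, settle_time * 2, 1.0, 1.0, 0.0, H_SPLIT
    )
    y_end = Y[-1]
    dy = np.empty(5)
    _kernels.rhs_cc(0.0, y_end, P, 0.0, dy)
    converged = ok and float(np.linalg.norm(dy)) < rate_tol
    return y_end, converged


def simulate_ramp(
    cable: CableParameters,
    sys: SystemProperties,
    active: ActiveParameters,
    ramp: RampProtocol | None = None,
    dt_out: float = DT_OUT,
    method: str = "split",
    h: float = H_SPLIT,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> StateTrajectory:
    """Run the triangular current-clamp protocol and return the sampled trajectory.

    ``method="split"`` (default) uses the fixed-step Strang-split exponential
    integrator, which is unconditionally stable against the stiff dendritic
    and gating time scales; ``method="dp54"`` uses the adaptive explicit
    Dormand-Prince pair (accurate but slow or divergent for very stiff cable
    tuples) and serves as a cross-check.
    """
    if not cable.valid:
        raise ValueError("simulate_ramp requires a valid cable")
    ramp = ramp or RampProtocol()
    P = _pack(cable, sys, active)
    y0 = _rest_initial_state(active)
    half = ramp.duration / 2.0
    if method == "split":
        t, Y, i_s, ok = _kernels.integrate_cc_split(
            P, y0, ramp.t_end, dt_out, ramp.pre_relax, half, half, ramp.peak, h
        )
    elif method == "dp54":
        t, Y, i_s, ok = _kernels.integrate_cc(
            P, y0, ramp.t_end, dt_out, ramp.pre_relax, half, half, ramp.peak,
            rtol, atol,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return StateTrajectory(
        t=t, v_s=Y[:, 0], v_d=Y[:, 1], n_s=Y[:, 2], m_d=Y[:, 3], n_d=Y[:, 4],
        i_s=i_s, valid=ok and bool(np.all(np.isfinite(Y))),
    )


def _vclamp_run(
    cable: CableParameters,
    sys: SystemProperties,
    active: ActiveParameters,
    vclamp: VClampProtocol,
    dt_out: float,
    method: str,
    h: float,
    rtol: float,
    atol: float,
) -> tuple[StateTrajectory, bool]:
    P = _pack(cable, sys, active)
    n_s0, m_d0, n_d0 = gating_steady_state(vclamp.v_base, active)
    y0 = np.array([vclamp.v_base, n_s0, m_d0, n_d0])
    half = vclamp.duration / 2.0
    if method == "split":
        t, Y, v_s, dvs, ok = _kernels.integrate_vc_split(
            P, y0, vclamp.t_end, dt_out, vclamp.pre_relax, half, half,
            vclamp.v_base, vclamp.v_peak, h,
        )
    elif method == "dp54":
        t, Y, v_s, dvs, ok = _kernels.integrate_vc(
            P, y0, vclamp.t_end, dt_out, vclamp.pre_relax, half, half,
            vclamp.v_base, vclamp.v_peak, rtol, atol,
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    v_d, n_s, m_d, n_d = Y[:, 0], Y[:, 1], Y[:, 2], Y[:, 3]
    ms_inf = 0.5 * (1.0 + np.tanh((v_s - active.v1s) / active.v2s))
    i_s = (
        cable.c_ms * dvs
        + cable.g_ms * (v_s - active.e_leak)
        + (cable.g_c / sys.p) * (v_s - v_d)
        + active.g_na * ms_inf * (v_s - active.e_na)
        + active.g_ks * n_s * (v_s - active.e_k)
    )
    traj = StateTrajectory(
        t=t, v_s=v_s, v_d=v_d, n_s=n_s, m_d=m_d, n_d=n_d, i_s=i_s,
        valid=ok and bool(np.all(np.isfinite(Y))),
    )
    return traj, ok


def simulate_vclamp(
    cable: CableParameters,
    sys: SystemProperties,
    active: ActiveParameters,
    vclamp: VClampProtocol | None = None,
    dt_out: float = DT_OUT,
    method: str = "split",
    h: float = H_SPLIT,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> tuple[StateTrajectory, np.ndarray]:
    """Triangular somatic voltage clamp; returns (trajectory, PIC current trace).

    The soma follows the commanded triangle exactly while the dendrite and
    all gates evolve freely.  The measured clamp current ``i_s`` includes the
    capacitive term.  The PIC trace is ``I_S - I_leak`` where ``I_leak`` is
    the clamp current of an identical companion run with ``g_ca = 0`` (PIC
    blocked); the PIC is inward, so the trace is negative during activation.
    """
    vclamp = vclamp or VClampProtocol(v_base=active.e_leak)
    traj, _ = _vclamp_run(cable, sys, active, vclamp, dt_out, method, h, rtol, atol)
    if active.g_ca == 0.0:
        return traj, np.zeros_like(traj.i_s)
    blocked, _ = _vclamp_run(
        cable, sys, active.with_gca(0.0), vclamp, dt_out, method, h, rtol, atol
    )
    return traj, traj.i_s - blocked.i_s
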