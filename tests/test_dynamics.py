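"""Model dynamics: fixed points, passive limits, solver cross-checks."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from motopic import (
    ActiveParameters,
    RampProtocol,
    VAFactors,
    VClampProtocol,
    derivatives,
    find_rest,
    invert_cable_parameters,
    simulate_ramp,
    simulate_vclamp,
)
from motopic.dynamics import gating_steady_state
from motopic.firing_analysis import detect_spikes


@pytest.fixture(scope="module")
def iv_cable(sysp):
    return invert_cable_parameters(sysp, VAFactors(0.94, 0.38, 0.69))


def test_rest_is_near_fixed_point(iv_cable, sysp, active):
    """Zero-stimulus relaxation settles near the leak potential with tiny rates."""
    state, converged = find_rest(iv_cable, sysp, active)
    assert converged
    assert state[0] == pytest.approx(-0.5, abs=0.05)
    rates = derivatives(state, 0.0, iv_cable, sysp, active, 0.0)
    assert np.linalg.norm(rates) < 1e-6


def test_rest_exact_without_active_conductances(iv_cable, sysp):
    """With all active conductances zero, rest is exactly (e_leak, e_leak)."""
    passive = ActiveParameters(g_na=0.0, g_ks=0.0, g_ca=0.0, g_kd=0.0)
    state, converged = find_rest(iv_cable, sysp, passive)
    assert converged
    assert state[0] == pytest.approx(-0.5, abs=1e-9)
    assert state[1] == pytest.approx(-0.5, abs=1e-9)


def test_passive_steady_state_matches_input_resistance(iv_cable, sysp):
    """A passive model under constant current settles at e_leak + I * r_input.

    r_input comes from the independent forward circuit computation, so this
    ties the simulated dynamics to the cable algebra.
    """
    from motopic import forward_system_properties

    passive = ActiveParameters(g_na=0.0, g_ks=0.0, g_ca=0.0, g_kd=0.0)
    _, r_n, _ = forward_system_properties(iv_cable, sysp)
    i_const = 1.0
    # slow, long ramp approximates constant current at its peak
    ramp = RampProtocol(peak=i_const, duration=4000.0, pre_relax=100.0)
    traj = simulate_ramp(iv_cable, sysp, passive, ramp)
    at_peak = np.argmin(np.abs(traj.t - ramp.t_peak))
    assert traj.v_s[at_peak] == pytest.approx(-0.5 + i_const * r_n, rel=2e-2)


def test_dendritic_half_activation_at_v1d(iv_cable, sysp, active):
    """At V_D = v1d the PIC activation rate drives m_D toward exactly 1/2."""
    state = np.array([-0.5, active.v1d, 0.0, 0.5, 0.0])
    rates = derivatives(state, 0.0, iv_cable, sysp, active, 0.0)
    assert rates[3] == pytest.approx(0.0, abs=1e-12)  # m_d already at m_inf = 0.5


def test_gating_variables_stay_in_unit_interval(exemplar_runs):
    """All gates remain within [0, 1] over every exemplar integration."""
    for _, traj, _ in exemplar_runs.values():
        for g in (traj.n_s, traj.m_d, traj.n_d):
            assert g.min() >= -1e-9
            assert g.max() <= 1.0 + 1e-9


def test_split_integrator_matches_lsoda(iv_cable, sysp, active, ramp):
    """Spike times from the split integrator agree with scipy's LSODA.

    LSODA integrates the same right-hand side independently (different
    method, different code path), so agreement validates both the compiled
    kernel and the splitting scheme.
    """
    traj = simulate_ramp(iv_cable, sysp, active, ramp)

    def rhs(t, y):
        i_app = float(ramp.current(t))
        return derivatives(y, t, iv_cable, sysp, active, i_app)

    n_s0, m_d0, n_d0 = gating_steady_state(active.e_leak, active)
    y0 = [active.e_leak, active.e_leak, n_s0, m_d0, n_d0]
    t_eval = np.arange(0.0, ramp.t_end + 1e-9, 0.1)
    sol = solve_ivp(
        rhs, (0, ramp.t_end), y0, t_eval=t_eval, method="LSODA",
        rtol=1e-8, atol=1e-10, max_step=10.0,
    )
    ref = traj.__class__(
        t=sol.t, v_s=sol.y[0], v_d=sol.y[1], n_s=sol.y[2],
        m_d=sol.y[3], n_d=sol.y[4], i_s=np.asarray(ramp.current(sol.t)),
    )
    sp = detect_spikes(traj).spike_times
    sp_ref = detect_spikes(ref).spike_times
    assert len(sp) == len(sp_ref)
    assert np.max(np.abs(sp - sp_ref)) < 0.5


def test_step_halving_convergence(iv_cable, sysp, active, ramp):
    """Halving the integration step moves spike times by < 0.5 time units."""
    sp = {}
    for h in (0.05, 0.025):
        traj = simulate_ramp(iv_cable, sysp, active, ramp, h=h)
        sp[h] = detect_spikes(traj).spike_times
    n = min(len(sp[0.05]), len(sp[0.025]))
    assert len(sp[0.05]) == len(sp[0.025])
    assert np.max(np.abs(sp[0.05][:n] - sp[0.025][:n])) < 0.5


def test_vclamp_pic_identities(iv_cable, sysp, active):
    """PIC trace is identically zero with g_ca = 0 and bounded by the Ohmic term."""
    vc = VClampProtocol()
    _, pic0 = simulate_vclamp(iv_cable, sysp, active.with_gca(0.0), vc)
    assert np.all(pic0 == 0.0)

    traj, pic = simulate_vclamp(iv_cable, sysp, active, vc)
    bound = active.g_ca * np.max(np.abs(traj.v_d - active.e_ca))
    assert np.max(np.abs(pic)) <= bound * (1.0 + 1e-6)
    # the PIC is an inward (negative) current during activation
    assert pic.min() < -0.1


def test_zero_peak_ramp_stays_at_rest(iv_cable, sysp, active):
    """With no stimulus the trajectory never spikes."""
    ramp = RampProtocol(peak=0.0, duration=3000.0)
    traj = simulate_ramp(iv_cable, sysp, active, ramp)
    assert len(detect_spikes(traj)) == 0
    assert np.max(traj.v_s) < -0.4


def test_invalid_cable_rejected(sysp, active):
    cable = invert_cable_parameters(sysp, VAFactors(1.0, 1.0, 0.5))
    with pytest.raises(ValueError):
        simulate_ramp(cable, sysp, active)


def test_active_parameter_validation():
    with pytest.raises(ValueError):
        ActiveParameters(v2d=-0.1)
    with pytest.raises(ValueError):
        ActiveParameters(g_na=-1.0)
    with pytest.raises(ValueError):
        VClampProtocol(v_base=0.5, v_peak=0.0)
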