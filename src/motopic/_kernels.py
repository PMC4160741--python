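"""Numba-compiled right-hand sides and adaptive Dormand-Prince integrators.

The model is a five-state ODE (V_S, V_D, n_S, m_D, n_D) that has to be
integrated over ~3500 time units for every point of a three-dimensional
parameter sweep, so the hot loop lives here.  The public modules
(:mod:`motopic.dynamics`) wrap these kernels and also provide a plain-NumPy
reference right-hand side; the two are cross-checked in the test suite.

Parameter packing (``P`` vector, length 21)::

    0..4   g_ms, g_md, g_c, c_ms, c_md
    5      p
    6..9   g_na, g_ks, g_ca, g_kd
    10..13 e_na, e_k, e_ca, e_leak
    14..15 v1d, v2d
    16     phi
    17..18 v1s, v2s            (somatic m_inf offset/slope; m_inf at -v1s)
    19..20 tau_md_v1, tau_md_v2 (dendritic m time-constant constants)

Somatic n gating uses fixed printed constants (offset 0.04, slope 0.1) and the
dendritic n gating uses (offset 0, slope 0.1); they are hard-wired in the
kernels because no analysis in this package varies them.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Dormand-Prince 5(4) coefficients.
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
# b - b_hat (error weights, including k7 term)
_E1, _E3, _E4, _E5, _E6, _E7 = (
    35.0 / 384.0 - 5179.0 / 57600.0,
    500.0 / 1113.0 - 7571.0 / 16695.0,
    125.0 / 192.0 - 393.0 / 640.0,
    -2187.0 / 6784.0 + 92097.0 / 339200.0,
    11.0 / 84.0 - 187.0 / 2100.0,
    -1.0 / 40.0,
)


@njit(cache=True)
def ramp_current(t, pre, rise, fall, peak):
    """Triangular current command: 0 until ``pre``, up to ``peak``, back to 0."""
    tt = t - pre
    if tt <= 0.0:
        return 0.0
    if tt < rise:
        return peak * tt / rise
    if tt < rise + fall:
        return peak * (rise + fall - tt) / fall
    return 0.0


@njit(cache=True)
def rhs_cc(t, y, P, i_app, dy):
    """Current-clamp right-hand side; writes rates into ``dy``."""
    g_ms, g_md, g_c, c_ms, c_md = P[0], P[1], P[2], P[3], P[4]
    p = P[5]
    g_na, g_ks, g_ca, g_kd = P[6], P[7], P[8], P[9]
    e_na, e_k, e_ca, e_leak = P[10], P[11], P[12], P[13]
    v1d, v2d, phi = P[14], P[15], P[16]
    v1s, v2s = P[17], P[18]
    tmd1, tmd2 = P[19], P[20]

    v_s, v_d, n_s, m_d, n_d = y[0], y[1], y[2], y[3], y[4]

    ms_inf = 0.5 * (1.0 + np.tanh((v_s - v1s) / v2s))
    dy[0] = (
        -g_ms * (v_s - e_leak)
        - (g_c / p) * (v_s - v_d)
        - g_na * ms_inf * (v_s - e_na)
        - g_ks * n_s * (v_s - e_k)
        + i_app
    ) / c_ms

    dy[1] = (
        -g_md * (v_d - e_leak)
        - (g_c / (1.0 - p)) * (v_d - v_s)
        - g_ca * m_d * (v_d - e_ca)
        - g_kd * n_d * (v_d - e_k)
    ) / c_md

    ns_inf = 0.5 * (1.0 + np.tanh((v_s + 0.04) / 0.1))
    dy[2] = phi * (ns_inf - n_s) * np.cosh((v_s + 0.04) / 0.1)

    md_inf = 0.5 * (1.0 + np.tanh((v_d - v1d) / v2d))
    dy[3] = phi * (md_inf - m_d) * np.cosh((v_d - tmd1) / tmd2)

    nd_inf = 0.5 * (1.0 + np.tanh(v_d / 0.1))
    dy[4] = phi * (nd_inf - n_d) * np.cosh(v_d / 0.1)


@njit(cache=True)
def rhs_vc(t, y, P, v_s, dy):
    """Voltage-clamp right-hand side: soma held at ``v_s``; state (V_D, n_S, m_D, n_D)."""
    g_md, g_c, c_md = P[1], P[2], P[4]
    p = P[5]
    g_ca, g_kd = P[8], P[9]
    e_k, e_ca, e_leak = P[11], P[12], P[13]
    v1d, v2d, phi = P[14], P[15], P[16]
    tmd1, tmd2 = P[19], P[20]

    v_d, n_s, m_d, n_d = y[0], y[1], y[2], y[3]

    dy[0] = (
        -g_md * (v_d - e_leak)
        - (g_c / (1.0 - p)) * (v_d - v_s)
        - g_ca * m_d * (v_d - e_ca)
        - g_kd * n_d * (v_d - e_k)
    ) / c_md

    ns_inf = 0.5 * (1.0 + np.tanh((v_s + 0.04) / 0.1))
    dy[1] = phi * (ns_inf - n_s) * np.cosh((v_s + 0.04) / 0.1)

    md_inf = 0.5 * (1.0 + np.tanh((v_d - v1d) / v2d))
    dy[2] = phi * (md_inf - m_d) * np.cosh((v_d - tmd1) / tmd2)

    nd_inf = 0.5 * (1.0 + np.tanh(v_d / 0.1))
    dy[3] = phi * (nd_inf - n_d) * np.cosh(v_d / 0.1)


@njit(cache=True)
def vclamp_command(t, pre, rise, fall, v_base, v_peak):
    """Triangular somatic voltage command (hold at v_base before the ramp)."""
    tt = t - pre
    if tt <= 0.0:
        return v_base
    if tt < rise:
        return v_base + (v_peak - v_base) * tt / rise
    if tt < rise + fall:
        return v_base + (v_peak - v_base) * (rise + fall - tt) / fall
    return v_base


@njit(cache=True)
def _error_norm(err, y0, y1, rtol, atol, n):
    s = 0.0
    for i in range(n):
        sc = atol + rtol * max(abs(y0[i]), abs(y1[i]))
        e = err[i] / sc
        s += e * e
    return np.sqrt(s / n)


@njit(cache=True)
def integrate_cc(P, y0, t_end, dt_out, pre, rise, fall, peak, rtol, atol):
    """Integrate the current-clamp model from t=0 to ``t_end``.

    Adaptive Dormand-Prince 5(4) with cubic-Hermite interpolation onto a
    uniform output grid of spacing ``dt_out``.  Steps never straddle the
    slope breakpoints of the triangular command.  Returns
    ``(t_grid, Y (n_out x 5), i_s, ok)``; ``ok`` is False when the step size
    underflows (integration failure).
    """
    n = 5
    n_out = int(round(t_end / dt_out)) + 1
    tgrid = np.empty(n_out)
    for i in range(n_out):
        tgrid[i] = i * dt_out
    Y = np.empty((n_out, n))
    i_s = np.empty(n_out)
    for i in range(n_out):
        i_s[i] = ramp_current(tgrid[i], pre, rise, fall, peak)

    # slope breakpoints of the stimulus
    bps = np.array([pre, pre + rise, pre + rise + fall, t_end + 1.0])

    y = y0.copy()
    t = 0.0
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); ynew = np.empty(n); err = np.empty(n)

    rhs_cc(t, y, P, ramp_current(t, pre, rise, fall, peak), k1)
    Y[0] = y
    iout = 1
    h = 1e-3
    hmax = 10.0
    hmin = 1e-10
    ok = True
    ibp = 0
    while t < t_end:
        while bps[ibp] <= t + 1e-12:
            ibp += 1
        if h > hmax:
            h = hmax
        if t + h > bps[ibp]:
            h = bps[ibp] - t
        if t + h > t_end:
            h = t_end - t

        for i in range(n):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        rhs_cc(t + h / 5.0, ytmp, P, ramp_current(t + h / 5.0, pre, rise, fall, peak), k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        rhs_cc(t + 0.3 * h, ytmp, P, ramp_current(t + 0.3 * h, pre, rise, fall, peak), k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs_cc(t + 0.8 * h, ytmp, P, ramp_current(t + 0.8 * h, pre, rise, fall, peak), k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
            )
        rhs_cc(
            t + 8.0 * h / 9.0, ytmp, P,
            ramp_current(t + 8.0 * h / 9.0, pre, rise, fall, peak), k5,
        )
        for i in range(n):
            ytmp[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        rhs_cc(t + h, ytmp, P, ramp_current(t + h, pre, rise, fall, peak), k6)
        for i in range(n):
            ynew[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        rhs_cc(t + h, ynew, P, ramp_current(t + h, pre, rise, fall, peak), k7)
        for i in range(n):
            err[i] = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                + _E6 * k6[i] + _E7 * k7[i]
            )
        enorm = _error_norm(err, y, ynew, rtol, atol, n)

        if enorm <= 1.0:
            tnew = t + h
            # cubic Hermite fill of output samples in (t, tnew]
            while iout < n_out and tgrid[iout] <= tnew + 1e-12:
                s = (tgrid[iout] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for i in range(n):
                    Y[iout, i] = (
                        h00 * y[i] + h10 * h * k1[i]
                        + h01 * ynew[i] + h11 * h * k7[i]
                    )
                iout += 1
            t = tnew
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL

        fac = 2.0
        if enorm > 0.0:
            fac = 0.9 * enorm ** (-0.2)
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < hmin:
            ok = False
            break
    return tgrid, Y, i_s, ok


@njit(cache=True)
def integrate_vc(P, y0, t_end, dt_out, pre, rise, fall, v_base, v_peak, rtol, atol):
    """Integrate the voltage-clamp model (state V_D, n_S, m_D, n_D).

    Returns ``(t_grid, Y (n_out x 4), v_s, dvs_dt, ok)`` where ``v_s`` is the
    prescribed somatic command sampled on the output grid and ``dvs_dt`` its
    (piecewise-constant) slope, needed for the capacitive term of the
    measured clamp current.
    """
    n = 4
    n_out = int(round(t_end / dt_out)) + 1
    tgrid = np.empty(n_out)
    vs_out = np.empty(n_out)
    dvs_out = np.empty(n_out)
    for i in range(n_out):
        tgrid[i] = i * dt_out
        vs_out[i] = vclamp_command(tgrid[i], pre, rise, fall, v_base, v_peak)
        tt = tgrid[i] - pre
        if tt <= 0.0 or tt >= rise + fall:
            dvs_out[i] = 0.0
        elif tt < rise:
            dvs_out[i] = (v_peak - v_base) / rise
        else:
            dvs_out[i] = -(v_peak - v_base) / fall
    Y = np.empty((n_out, n))

    bps = np.array([pre, pre + rise, pre + rise + fall, t_end + 1.0])
    y = y0.copy()
    t = 0.0
    k1 = np.empty(n); k2 = np.empty(n); k3 = np.empty(n); k4 = np.empty(n)
    k5 = np.empty(n); k6 = np.empty(n); k7 = np.empty(n)
    ytmp = np.empty(n); ynew = np.empty(n); err = np.empty(n)

    rhs_vc(t, y, P, vclamp_command(t, pre, rise, fall, v_base, v_peak), k1)
    Y[0] = y
    iout = 1
    h = 1e-3
    hmax = 10.0
    hmin = 1e-10
    ok = True
    ibp = 0
    while t < t_end:
        while bps[ibp] <= t + 1e-12:
            ibp += 1
        if h > hmax:
            h = hmax
        if t + h > bps[ibp]:
            h = bps[ibp] - t
        if t + h > t_end:
            h = t_end - t

        for i in range(n):
            ytmp[i] = y[i] + h * _A21 * k1[i]
        rhs_vc(t + h / 5.0, ytmp, P,
               vclamp_command(t + h / 5.0, pre, rise, fall, v_base, v_peak), k2)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        rhs_vc(t + 0.3 * h, ytmp, P,
               vclamp_command(t + 0.3 * h, pre, rise, fall, v_base, v_peak), k3)
        for i in range(n):
            ytmp[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs_vc(t + 0.8 * h, ytmp, P,
               vclamp_command(t + 0.8 * h, pre, rise, fall, v_base, v_peak), k4)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                _A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i]
            )
        rhs_vc(t + 8.0 * h / 9.0, ytmp, P,
               vclamp_command(t + 8.0 * h / 9.0, pre, rise, fall, v_base, v_peak), k5)
        for i in range(n):
            ytmp[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        rhs_vc(t + h, ytmp, P,
               vclamp_command(t + h, pre, rise, fall, v_base, v_peak), k6)
        for i in range(n):
            ynew[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        rhs_vc(t + h, ynew, P,
               vclamp_command(t + h, pre, rise, fall, v_base, v_peak), k7)
        for i in range(n):
            err[i] = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i]
                + _E6 * k6[i] + _E7 * k7[i]
            )
        enorm = _error_norm(err, y, ynew, rtol, atol, n)

        if enorm <= 1.0:
            tnew = t + h
            while iout < n_out and tgrid[iout] <= tnew + 1e-12:
                s = (tgrid[iout] - t) / h
                h00 = (1.0 + 2.0 * s) * (1.0 - s) ** 2
                h10 = s * (1.0 - s) ** 2
                h01 = s * s * (3.0 - 2.0 * s)
                h11 = s * s * (s - 1.0)
                for i in range(n):
                    Y[iout, i] = (
                        h00 * y[i] + h10 * h * k1[i]
                        + h01 * ynew[i] + h11 * h * k7[i]
                    )
                iout += 1
            t = tnew
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]

        fac = 2.0
        if enorm > 0.0:
            fac = 0.9 * enorm ** (-0.2)
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < hmin:
            ok = False
            break
    return tgrid, Y, vs_out, dvs_out, ok


@njit(cache=True)
def _gate_relax(x, x_inf, rate, h):
    """Exact relaxation of a first-order gate over time h at frozen voltage."""
    return x_inf + (x - x_inf) * np.exp(-rate * h)


@njit(cache=True)
def _gates_half_step(y, P, h2):
    """Advance (n_S, m_D, n_D) exactly over h2 with the voltages frozen."""
    v_s, v_d = y[0], y[1]
    phi = P[16]
    v1d, v2d = P[14], P[15]
    tmd1, tmd2 = P[19], P[20]

    ns_inf = 0.5 * (1.0 + np.tanh((v_s + 0.04) / 0.1))
    y[2] = _gate_relax(y[2], ns_inf, phi * np.cosh((v_s + 0.04) / 0.1), h2)

    md_inf = 0.5 * (1.0 + np.tanh((v_d - v1d) / v2d))
    y[3] = _gate_relax(y[3], md_inf, phi * np.cosh((v_d - tmd1) / tmd2), h2)

    nd_inf = 0.5 * (1.0 + np.tanh(v_d / 0.1))
    y[4] = _gate_relax(y[4], nd_inf, phi * np.cosh(v_d / 0.1), h2)


@njit(cache=True)
def _voltages_linear_step(y, P, h, i_mid, ms_inf, out):
    """Exact update of (V_S, V_D) over h with gates and ``ms_inf`` frozen.

    The frozen subsystem is dv/dt = M v + b with a real-eigenvalue 2x2 matrix
    (positive off-diagonal coupling), so the matrix exponential is evaluated
    in closed form; stiffness from small C_m,D is handled exactly.  Writes
    the new voltage pair into ``out``.
    """
    g_ms, g_md, g_c, c_ms, c_md = P[0], P[1], P[2], P[3], P[4]
    p = P[5]
    g_na, g_ks, g_ca, g_kd = P[6], P[7], P[8], P[9]
    e_na, e_k, e_ca, e_leak = P[10], P[11], P[12], P[13]

    v_s, v_d, n_s, m_d, n_d = y[0], y[1], y[2], y[3], y[4]

    m11 = -(g_ms + g_c / p + g_na * ms_inf + g_ks * n_s) / c_ms
    m12 = (g_c / p) / c_ms
    m21 = (g_c / (1.0 - p)) / c_md
    m22 = -(g_md + g_c / (1.0 - p) + g_ca * m_d + g_kd * n_d) / c_md
    b1 = (g_ms * e_leak + g_na * ms_inf * e_na + g_ks * n_s * e_k + i_mid) / c_ms
    b2 = (g_md * e_leak + g_ca * m_d * e_ca + g_kd * n_d * e_k) / c_md

    det = m11 * m22 - m12 * m21
    # fixed point v* = -M^{-1} b
    vs_star = (-m22 * b1 + m12 * b2) / det
    vd_star = (m21 * b1 - m11 * b2) / det

    d1 = v_s - vs_star
    d2 = v_d - vd_star

    tr = m11 + m22
    disc = tr * tr - 4.0 * det
    if disc < 0.0:
        disc = 0.0  # symmetrizable coupling: eigenvalues are real up to roundoff
    sq = np.sqrt(disc)
    lam1 = 0.5 * (tr + sq)
    lam2 = 0.5 * (tr - sq)
    e1 = np.exp(lam1 * h)
    e2 = np.exp(lam2 * h)
    if sq > 1e-12 * max(abs(lam1), 1.0):
        # expm(Mh) = e1*(M - lam2 I)/(lam1-lam2) + e2*(M - lam1 I)/(lam2-lam1)
        f = (e1 - e2) / sq
        g = (e1 + e2) * 0.5
        # expm = g*I + f*(M - 0.5*tr*I)
        a11 = g + f * (m11 - 0.5 * tr)
        a12 = f * m12
        a21 = f * m21
        a22 = g + f * (m22 - 0.5 * tr)
    else:
        lam = 0.5 * tr
        el = np.exp(lam * h)
        a11 = el * (1.0 + (m11 - lam) * h)
        a12 = el * m12 * h
        a21 = el * m21 * h
        a22 = el * (1.0 + (m22 - lam) * h)

    out[0] = vs_star + a11 * d1 + a12 * d2
    out[1] = vd_star + a21 * d1 + a22 * d2


@njit(cache=True)
def _voltages_full_step(y, P, h, i_mid, scratch):
    """Second-order voltage update: midpoint predictor for the somatic
    instantaneous activation, then the exact frozen-coefficient step."""
    v1s, v2s = P[17], P[18]
    ms0 = 0.5 * (1.0 + np.tanh((y[0] - v1s) / v2s))
    _voltages_linear_step(y, P, 0.5 * h, i_mid, ms0, scratch)
    ms_mid = 0.5 * (1.0 + np.tanh((scratch[0] - v1s) / v2s))
    _voltages_linear_step(y, P, h, i_mid, ms_mid, scratch)
    y[0] = scratch[0]
    y[1] = scratch[1]


@njit(cache=True)
def integrate_cc_split(P, y0, t_end, dt_out, pre, rise, fall, peak, h):
    """Fixed-step Strang-split exponential integration of the current-clamp model.

    Sequence per step: half-step exact gate relaxation, full-step exact
    frozen-coefficient voltage update (stimulus at the step midpoint),
    half-step gate relaxation.  ``h`` must divide ``dt_out``; output samples
    land exactly on step boundaries, as do the stimulus breakpoints for the
    default protocols.
    """
    n_out = int(round(t_end / dt_out)) + 1
    k_sub = int(round(dt_out / h))
    hh = dt_out / k_sub
    tgrid = np.empty(n_out)
    i_s = np.empty(n_out)
    for i in range(n_out):
        tgrid[i] = i * dt_out
        i_s[i] = ramp_current(tgrid[i], pre, rise, fall, peak)
    Y = np.empty((n_out, 5))
    y = y0.copy()
    scratch = np.empty(2)
    Y[0] = y
    ok = True
    for i in range(1, n_out):
        t = tgrid[i - 1]
        for k in range(k_sub):
            i_mid = ramp_current(t + (k + 0.5) * hh, pre, rise, fall, peak)
            _gates_half_step(y, P, 0.5 * hh)
            _voltages_full_step(y, P, hh, i_mid, scratch)
            _gates_half_step(y, P, 0.5 * hh)
        Y[i] = y
        if not (np.isfinite(y[0]) and np.isfinite(y[1])):
            ok = False
            break
    return tgrid, Y, i_s, ok


@njit(cache=True)
def integrate_vc_split(P, y0, t_end, dt_out, pre, rise, fall, v_base, v_peak, h):
    """Fixed-step split integration under somatic voltage clamp.

    State is (V_D, n_S, m_D, n_D); V_S follows the command exactly.  The
    dendritic voltage update is the exact scalar exponential relaxation with
    gates and V_S frozen at the step midpoint.
    """
    n_out = int(round(t_end / dt_out)) + 1
    k_sub = int(round(dt_out / h))
    hh = dt_out / k_sub
    tgrid = np.empty(n_out)
    vs_out = np.empty(n_out)
    dvs_out = np.empty(n_out)
    for i in range(n_out):
        tgrid[i] = i * dt_out
        vs_out[i] = vclamp_command(tgrid[i], pre, rise, fall, v_base, v_peak)
        tt = tgrid[i] - pre
        if tt <= 0.0 or tt >= rise + fall:
            dvs_out[i] = 0.0
        elif tt < rise:
            dvs_out[i] = (v_peak - v_base) / rise
        else:
            dvs_out[i] = -(v_peak - v_base) / fall
    Y = np.empty((n_out, 4))

    g_md, g_c, c_md = P[1], P[2], P[4]
    p = P[5]
    g_ca, g_kd = P[8], P[9]
    e_k, e_ca, e_leak = P[11], P[12], P[13]
    v1d, v2d, phi = P[14], P[15], P[16]
    tmd1, tmd2 = P[19], P[20]

    y = y0.copy()
    Y[0] = y
    ok = True
    for i in range(1, n_out):
        t = tgrid[i - 1]
        for k in range(k_sub):
            t_mid = t + (k + 0.5) * hh
            v_s = vclamp_command(t_mid, pre, rise, fall, v_base, v_peak)
            v_d = y[0]
            h2 = 0.5 * hh
            # half-step gates at frozen voltages
            ns_inf = 0.5 * (1.0 + np.tanh((v_s + 0.04) / 0.1))
            y[1] = _gate_relax(y[1], ns_inf, phi * np.cosh((v_s + 0.04) / 0.1), h2)
            md_inf = 0.5 * (1.0 + np.tanh((v_d - v1d) / v2d))
            y[2] = _gate_relax(y[2], md_inf, phi * np.cosh((v_d - tmd1) / tmd2), h2)
            nd_inf = 0.5 * (1.0 + np.tanh(v_d / 0.1))
            y[3] = _gate_relax(y[3], nd_inf, phi * np.cosh(v_d / 0.1), h2)
            # full-step dendritic voltage: linear relaxation at frozen gates
            g_tot = g_md + g_c / (1.0 - p) + g_ca * y[2] + g_kd * y[3]
            v_inf = (
                g_md * e_leak + (g_c / (1.0 - p)) * v_s
                + g_ca * y[2] * e_ca + g_kd * y[3] * e_k
            ) / g_tot
            y[0] = v_inf + (y[0] - v_inf) * np.exp(-g_tot * hh / c_md)
            # half-step gates at updated dendritic voltage
            v_d = y[0]
            y[1] = _gate_relax(y[1], ns_inf, phi * np.cosh((v_s + 0.04) / 0.1), h2)
            md_inf = 0.5 * (1.0 + np.tanh((v_d - v1d) / v2d))
            y[2] = _gate_relax(y[2], md_inf, phi * np.cosh((v_d - tmd1) / tmd2), h2)
            nd_inf = 0.5 * (1.0 + np.tanh(v_d / 0.1))
            y[3] = _gate_relax(y[3], nd_inf, phi * np.cosh(v_d / 0.1), h2)
        Y[i] = y
        if not np.isfinite(y[0]):
            ok = False
            break
    return tgrid, Y, vs_out, dvs_out, ok
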