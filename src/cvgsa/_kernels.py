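"""Batched adaptive Runge-Kutta integration of the cardiovascular models.

One Dormand-Prince 5(4) driver (numba-compiled, FSAL, PI-free standard step
control) integrates a whole design matrix of parameter draws sample-by-sample
and records the three measured channels on the saved steady-state cycle.
Rows whose step size collapses or whose state leaves the finite range are
flagged; ``evaluate_batch`` retries flagged rows once with a stiff-capable
scipy solver before reporting them failed.

The activation kernel uses sequential branching (rise while t < tau_es, fall
while t < tau_ep, else baseline), so parameter draws with inverted timing
values remain integrable (the activation then relaxes instantaneously at
tau_es); the strict API-level invariants live in :mod:`cvgsa.models`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from . import models

__all__ = ["evaluate_batch"]

_MAX_STEPS = 5_000_000


@njit(cache=True)
def _activation(t, tau, shift, tau_es, tau_ep):
    tt = (t - shift) % tau
    if tt < tau_es:
        return 0.5 * (1.0 - np.cos(np.pi * tt / tau_es))
    elif tt < tau_ep:
        return 0.5 * (1.0 + np.cos(np.pi * (tt - tau_es) / (tau_ep - tau_es)))
    return 0.0


@njit(cache=True)
def _rhs(model, t, y, p, tau, v0, shift_la, dy):
    if model == 0:
        e_max, e_min, tau_es, tau_ep = p[0], p[1], p[2], p[3]
        z_ao, r_mv, r_s, c_sa, c_sv = p[4], p[5], p[6], p[7], p[8]
        e = (e_max - e_min) * _activation(t, tau, 0.0, tau_es, tau_ep) + e_min
        p_lv = e * (y[0] - v0)
        q_mv = (y[2] - p_lv) / r_mv if y[2] > p_lv else 0.0
        q_av = (p_lv - y[1]) / z_ao if p_lv > y[1] else 0.0
        q_s = (y[1] - y[2]) / r_s
        dy[0] = q_mv - q_av
        dy[1] = (q_av - q_s) / c_sa
        dy[2] = (q_s - q_mv) / c_sv
    else:
        e_lv = (p[1] - p[0]) * _activation(t, tau, 0.0, p[2], p[3]) + p[0]
        e_la = (p[5] - p[4]) * _activation(t, tau, shift_la, p[6], p[7]) + p[4]
        z_ao, r_mv = p[8], p[9]
        c_sas, r_sas, l_sas = p[10], p[11], p[12]
        c_sat, r_sat, l_sat = p[13], p[14], p[15]
        r_ser = r_sat + p[16] + p[17]  # arterial + arteriolar + capillary
        r_svn, c_svn = p[18], p[19]
        p_lv = e_lv * (y[0] - v0)
        p_la = e_la * (y[1] - v0)
        q_mv = (p_la - p_lv) / r_mv if p_la > p_lv else 0.0
        q_av = (p_lv - y[2]) / z_ao if p_lv > y[2] else 0.0
        q_svn = (y[6] - p_la) / r_svn
        dy[0] = q_mv - q_av
        dy[1] = q_svn - q_mv
        dy[2] = (q_av - y[3]) / c_sas
        dy[3] = (y[2] - y[4] - r_sas * y[3]) / l_sas
        dy[4] = (y[3] - y[5]) / c_sat
        dy[5] = (y[4] - y[6] - r_ser * y[5]) / l_sat
        dy[6] = (y[5] - q_svn) / c_svn


@njit(cache=True)
def _solve_batch(model, theta, y_init, tau, v0, shift_la, rtol, atol,
                 t_saves, t_end, out, ok):
    """Integrate each parameter row; record (P_lv, P_art, V_lv) at t_saves."""
    nb = theta.shape[0]
    nd = y_init.shape[0]
    ns = t_saves.shape[0]
    # Dormand-Prince 5(4) tableau
    c2, c3, c4, c5 = 0.2, 0.3, 0.8, 8.0 / 9.0
    a21 = 0.2
    a31, a32 = 3.0 / 40.0, 9.0 / 40.0
    a41, a42, a43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
    a51, a52, a53, a54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
    a61, a62, a63, a64, a65 = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
                               49.0 / 176.0, -5103.0 / 18656.0)
    b1, b3, b4, b5, b6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
    e1, e3, e4, e5, e6, e7 = (71.0 / 57600.0, -71.0 / 16695.0, 71.0 / 1920.0,
                              -17253.0 / 339200.0, 22.0 / 525.0, -1.0 / 40.0)
    hmin = 1e-13 * tau
    for b in range(nb):
        p = theta[b]
        y = y_init.copy()
        ytmp = np.empty(nd)
        k1 = np.empty(nd); k2 = np.empty(nd); k3 = np.empty(nd)
        k4 = np.empty(nd); k5 = np.empty(nd); k6 = np.empty(nd); k7 = np.empty(nd)
        t = 0.0
        h = 1e-4 * tau
        isave = 0
        _rhs(model, t, y, p, tau, v0, shift_la, k1)
        failed = False
        nsteps = 0
        while t < t_end:
            nsteps += 1
            if nsteps > _MAX_STEPS or h < hmin:
                failed = True
                break
            # clamp the step onto the next save point / final time
            t_target = t_end
            if isave < ns and t_saves[isave] < t_target:
                t_target = t_saves[isave]
            if t + h > t_target:
                h = t_target - t
            # stages (k1 holds f(t, y) from FSAL)
            for i in range(nd):
                ytmp[i] = y[i] + h * a21 * k1[i]
            _rhs(model, t + c2 * h, ytmp, p, tau, v0, shift_la, k2)
            for i in range(nd):
                ytmp[i] = y[i] + h * (a31 * k1[i] + a32 * k2[i])
            _rhs(model, t + c3 * h, ytmp, p, tau, v0, shift_la, k3)
            for i in range(nd):
                ytmp[i] = y[i] + h * (a41 * k1[i] + a42 * k2[i] + a43 * k3[i])
            _rhs(model, t + c4 * h, ytmp, p, tau, v0, shift_la, k4)
            for i in range(nd):
                ytmp[i] = y[i] + h * (a51 * k1[i] + a52 * k2[i] + a53 * k3[i] + a54 * k4[i])
            _rhs(model, t + c5 * h, ytmp, p, tau, v0, shift_la, k5)
            for i in range(nd):
                ytmp[i] = y[i] + h * (a61 * k1[i] + a62 * k2[i] + a63 * k3[i]
                                      + a64 * k4[i] + a65 * k5[i])
            _rhs(model, t + h, ytmp, p, tau, v0, shift_la, k6)
            for i in range(nd):
                ytmp[i] = y[i] + h * (b1 * k1[i] + b3 * k3[i] + b4 * k4[i]
                                      + b5 * k5[i] + b6 * k6[i])
            _rhs(model, t + h, ytmp, p, tau, v0, shift_la, k7)
            # scaled RMS error of the embedded 4th-order solution
            err = 0.0
            bad = False
            for i in range(nd):
                if not np.isfinite(ytmp[i]):
                    bad = True
                    break
                de = h * (e1 * k1[i] + e3 * k3[i] + e4 * k4[i]
                          + e5 * k5[i] + e6 * k6[i] + e7 * k7[i])
                sc = atol + rtol * max(abs(y[i]), abs(ytmp[i]))
                err += (de / sc) ** 2
            if bad:
                failed = True
                break
            err = np.sqrt(err / nd)
            if err <= 1.0:
                t_new = t + h
                for i in range(nd):
                    y[i] = ytmp[i]
                for i in range(nd):
                    k1[i] = k7[i]  # FSAL
                t = t_new
                if isave < ns and t >= t_saves[isave]:
                    # record measurement channels at the save point
                    if model == 0:
                        e = (p[0] - p[1]) * _activation(t, tau, 0.0, p[2], p[3]) + p[1]
                        out[b, 0, isave] = e * (y[0] - v0)
                        out[b, 1, isave] = y[1]
                        out[b, 2, isave] = y[0]
                    else:
                        e = (p[1] - p[0]) * _activation(t, tau, 0.0, p[2], p[3]) + p[0]
                        out[b, 0, isave] = e * (y[0] - v0)
                        out[b, 1, isave] = y[4]
                        out[b, 2, isave] = y[0]
                    isave += 1
            # step-size update (standard 5th-order controller)
            if err == 0.0:
                fac = 5.0
            else:
                fac = 0.9 * err ** -0.2
                if fac < 0.2:
                    fac = 0.2
                elif fac > 5.0:
                    fac = 5.0
            h = h * fac
        ok[b] = not failed and isave == ns
        if not ok[b]:
            for j in range(3):
                for i in range(ns):
                    out[b, j, i] = np.nan


def _stiff_fallback(model_id, row, constants, solver, t_saves, t_end):
    """One scipy BDF attempt for a kernel-flagged parameter row.

    Uses the same compiled right-hand side and tolerant activation as the
    batch kernel, so kernel and fallback integrate identical dynamics.
    """
    from scipy.integrate import solve_ivp

    model = 0 if model_id == "one_chamber" else 1
    tau, v0, shift = constants.tau, constants.v0, constants.e_shift

    def f(t, y):
        dy = np.empty_like(y)
        _rhs(model, t, y, row, tau, v0, shift, dy)
        return dy

    y0 = np.array(constants.initial_state or models.DEFAULT_STATE[model_id], dtype=float)
    try:
        sol = solve_ivp(f, (0.0, t_end), y0, method="BDF", t_eval=t_saves,
                        rtol=solver.rtol, atol=solver.atol)
    except FloatingPointError:
        return None
    if not sol.success or not np.all(np.isfinite(sol.y)):
        return None
    ys = sol.y
    if model == 0:
        e_max, e_min, tes, tep = row[0], row[1], row[2], row[3]
    else:
        e_min, e_max, tes, tep = row[0], row[1], row[2], row[3]
    act = np.array([_activation(t, tau, 0.0, tes, tep) for t in t_saves])
    p_lv = ((e_max - e_min) * act + e_min) * (ys[0] - v0)
    return np.stack([p_lv, ys[1] if model == 0 else ys[4], ys[0]])


def evaluate_batch(model_id: str, theta: np.ndarray,
                   constants: models.ModelConstants | None = None,
                   solver: models.SolverSettings | None = None):
    """Integrate every parameter row of ``theta`` (B, n).

    Returns ``(waves, ok)`` where ``waves`` is (B, 3, points_per_cycle) with
    channels (P_lv, P_art, V_lv) on the saved cycle and ``ok`` flags rows
    that integrated successfully (failed rows are NaN).
    """
    c = constants or models.default_constants(model_id)
    s = solver or models.SolverSettings()
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    model = 0 if model_id == "one_chamber" else 1
    y0 = np.array(c.initial_state or models.DEFAULT_STATE[model_id], dtype=np.float64)
    t0 = c.n_transient * c.tau
    t_end = c.n_cycles * c.tau
    t_saves = t0 + c.tau * np.arange(s.points_per_cycle) / s.points_per_cycle
    nb = theta.shape[0]
    out = np.empty((nb, 3, s.points_per_cycle))
    ok = np.empty(nb, dtype=np.bool_)
    _solve_batch(model, theta, y0, c.tau, c.v0, c.e_shift,
                 s.rtol, s.atol, t_saves, t_end, out, ok)
    for b in np.flatnonzero(~ok):
        res = _stiff_fallback(model_id, theta[b], c, s, t_saves, t_end)
        if res is not None:
            out[b] = res
            ok[b] = True
    return out, ok
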