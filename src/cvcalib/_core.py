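"""Compiled right-hand side and integrator for the closed-loop circulation.

The model is a system of 21 ODEs in compartment *stressed* volumes:

* heart chambers (RA, RV, LA, LV): time-varying elastance, p = E(t) q
* valves (trv, puv, miv, aov): ideal diode in series with a small
  resistance; max(dp, 0) is smoothed as (dp + sqrt(dp^2 + eps^2))/2 so
  valve flow is C-infinity and strictly positive
* vessel segments: linear compliance p = q/C with series resistances
* terminal beds: series resistance R_x_T feeding a terminal compliance,
  drained through a fixed venous return resistance
* venous compartments (upper/lower body): linear compliances that share
  the single venous compliance parameter C_V

Flows between compartments appear with opposite signs in exactly two
volume derivatives, so total stressed volume is conserved analytically;
the fixed-step RK4 scheme preserves this to rounding error.  Resistances
and compliances are constant within a run, so their reciprocals are
precomputed once per solve.

Everything here is numba-compiled; the public API lives in
:mod:`cvcalib.model`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Packed parameter vector layout (kept in sync with model.PACK_ORDER).
(
    I_Q_SBV, I_E_LVA, I_E_RVA, I_R_PAR,
    I_R_LE_T, I_R_BR_T, I_R_AC_T, I_R_EC_T, I_R_MC_T, I_R_PC_T, I_R_TR_T,
    I_C_V, I_T, I_T_SYS, I_T_ATR, I_ATR_ONSET,
    I_E_RAB, I_E_RAA, I_E_RVB, I_E_LAB, I_E_LAA, I_E_LVB,
    I_R_TRV, I_R_PUV, I_R_MIV, I_R_AOV, I_P_SMOOTH,
    I_C_PAR, I_C_PVN, I_R_PVN,
    I_C_AOR, I_C_UBR, I_C_CER, I_C_MCA, I_C_BRA, I_C_DAO,
    I_R_AOR_UBR, I_R_AOR_DAO, I_R_UBR_CER, I_R_UBR_BRA, I_R_CER_MCA,
    I_C_LE, I_C_BR, I_C_AC, I_C_EC, I_C_MC, I_C_PC, I_C_TR,
    I_RV_LE, I_RV_BR, I_RV_AC, I_RV_EC, I_RV_MC, I_RV_PC, I_RV_TR,
    I_F_VUB, I_R_SVC, I_R_IVC,
    I_Q0_RA, I_Q0_RV, I_Q0_LA, I_Q0_LV,
) = range(62)

N_PARAMS = 62
N_STATES = 21

# State vector layout (stressed volumes, m^3).
(
    X_RA, X_RV, X_LA, X_LV, X_PAR, X_PVN,
    X_AOR, X_UBR, X_CER, X_MCA, X_BRA, X_DAO,
    X_LE, X_BR, X_AC, X_EC, X_MC, X_PC, X_TR,
    X_VUB, X_VLB,
) = range(N_STATES)

# Derived-constant vector layout: reciprocal resistances and compliances.
(
    G_TRV, G_PUV, G_MIV, G_AOV,
    G_PAR, G_PVN,
    G_AOR_UBR, G_AOR_DAO, G_UBR_CER, G_UBR_BRA, G_CER_MCA,
    G_LE_T, G_BR_T, G_AC_T, G_EC_T, G_MC_T, G_PC_T, G_TR_T,
    G_LE_V, G_BR_V, G_AC_V, G_EC_V, G_MC_V, G_PC_V, G_TR_V,
    G_SVC, G_IVC,
    IC_PAR, IC_PVN,
    IC_AOR, IC_UBR, IC_CER, IC_MCA, IC_BRA, IC_DAO,
    IC_LE, IC_BR, IC_AC, IC_EC, IC_MC, IC_PC, IC_TR,
    IC_VUB, IC_VLB,
    D_PS2,
) = range(45)

N_DERIVED = 45


@njit(cache=True)
def activation(t, onset, dur, period):
    """Smooth periodic activation in [0, 1]: raised cosine over ``dur``."""
    tau = (t - onset) % period
    if tau < dur:
        return 0.5 * (1.0 - math.cos(2.0 * math.pi * tau / dur))
    return 0.0


@njit(cache=True)
def derive(p):
    """Precompute reciprocal conductances/compliances for one solve."""
    d = np.empty(N_DERIVED)
    d[G_TRV] = 1.0 / p[I_R_TRV]
    d[G_PUV] = 1.0 / p[I_R_PUV]
    d[G_MIV] = 1.0 / p[I_R_MIV]
    d[G_AOV] = 1.0 / p[I_R_AOV]
    d[G_PAR] = 1.0 / p[I_R_PAR]
    d[G_PVN] = 1.0 / p[I_R_PVN]
    d[G_AOR_UBR] = 1.0 / p[I_R_AOR_UBR]
    d[G_AOR_DAO] = 1.0 / p[I_R_AOR_DAO]
    d[G_UBR_CER] = 1.0 / p[I_R_UBR_CER]
    d[G_UBR_BRA] = 1.0 / p[I_R_UBR_BRA]
    d[G_CER_MCA] = 1.0 / p[I_R_CER_MCA]
    d[G_LE_T] = 1.0 / p[I_R_LE_T]
    d[G_BR_T] = 1.0 / p[I_R_BR_T]
    d[G_AC_T] = 1.0 / p[I_R_AC_T]
    d[G_EC_T] = 1.0 / p[I_R_EC_T]
    d[G_MC_T] = 1.0 / p[I_R_MC_T]
    d[G_PC_T] = 1.0 / p[I_R_PC_T]
    d[G_TR_T] = 1.0 / p[I_R_TR_T]
    d[G_LE_V] = 1.0 / p[I_RV_LE]
    d[G_BR_V] = 1.0 / p[I_RV_BR]
    d[G_AC_V] = 1.0 / p[I_RV_AC]
    d[G_EC_V] = 1.0 / p[I_RV_EC]
    d[G_MC_V] = 1.0 / p[I_RV_MC]
    d[G_PC_V] = 1.0 / p[I_RV_PC]
    d[G_TR_V] = 1.0 / p[I_RV_TR]
    d[G_SVC] = 1.0 / p[I_R_SVC]
    d[G_IVC] = 1.0 / p[I_R_IVC]
    d[IC_PAR] = 1.0 / p[I_C_PAR]
    d[IC_PVN] = 1.0 / p[I_C_PVN]
    d[IC_AOR] = 1.0 / p[I_C_AOR]
    d[IC_UBR] = 1.0 / p[I_C_UBR]
    d[IC_CER] = 1.0 / p[I_C_CER]
    d[IC_MCA] = 1.0 / p[I_C_MCA]
    d[IC_BRA] = 1.0 / p[I_C_BRA]
    d[IC_DAO] = 1.0 / p[I_C_DAO]
    d[IC_LE] = 1.0 / p[I_C_LE]
    d[IC_BR] = 1.0 / p[I_C_BR]
    d[IC_AC] = 1.0 / p[I_C_AC]
    d[IC_EC] = 1.0 / p[I_C_EC]
    d[IC_MC] = 1.0 / p[I_C_MC]
    d[IC_PC] = 1.0 / p[I_C_PC]
    d[IC_TR] = 1.0 / p[I_C_TR]
    d[IC_VUB] = 1.0 / (p[I_F_VUB] * p[I_C_V])
    d[IC_VLB] = 1.0 / ((1.0 - p[I_F_VUB]) * p[I_C_V])
    d[D_PS2] = p[I_P_SMOOTH] * p[I_P_SMOOTH]
    return d


@njit(cache=True, inline="always")
def _diode(dp, g, ps2):
    """Smoothed ideal diode: ~max(dp, 0)*g, strictly positive."""
    return 0.5 * (dp + math.sqrt(dp * dp + ps2)) * g


@njit(cache=True)
def rhs(t, x, p, d, dx):
    """Fill dx with dq/dt for the 21 compartment stressed volumes."""
    period = p[I_T]
    e_v = activation(t, 0.0, p[I_T_SYS], period)
    e_a = activation(t, p[I_ATR_ONSET], p[I_T_ATR], period)

    # chamber pressures (MPa)
    p_ra = (p[I_E_RAB] + (p[I_E_RAA] - p[I_E_RAB]) * e_a) * x[X_RA]
    p_rv = (p[I_E_RVB] + (p[I_E_RVA] - p[I_E_RVB]) * e_v) * x[X_RV]
    p_la = (p[I_E_LAB] + (p[I_E_LAA] - p[I_E_LAB]) * e_a) * x[X_LA]
    p_lv = (p[I_E_LVB] + (p[I_E_LVA] - p[I_E_LVB]) * e_v) * x[X_LV]

    # vessel / terminal / venous pressures
    p_par = x[X_PAR] * d[IC_PAR]
    p_pvn = x[X_PVN] * d[IC_PVN]
    p_aor = x[X_AOR] * d[IC_AOR]
    p_ubr = x[X_UBR] * d[IC_UBR]
    p_cer = x[X_CER] * d[IC_CER]
    p_mca = x[X_MCA] * d[IC_MCA]
    p_bra = x[X_BRA] * d[IC_BRA]
    p_dao = x[X_DAO] * d[IC_DAO]
    p_le = x[X_LE] * d[IC_LE]
    p_br = x[X_BR] * d[IC_BR]
    p_ac = x[X_AC] * d[IC_AC]
    p_ec = x[X_EC] * d[IC_EC]
    p_mc = x[X_MC] * d[IC_MC]
    p_pc = x[X_PC] * d[IC_PC]
    p_tr = x[X_TR] * d[IC_TR]
    p_vub = x[X_VUB] * d[IC_VUB]
    p_vlb = x[X_VLB] * d[IC_VLB]

    ps2 = d[D_PS2]
    # valve flows (m^3/s)
    v_trv = _diode(p_ra - p_rv, d[G_TRV], ps2)
    v_puv = _diode(p_rv - p_par, d[G_PUV], ps2)
    v_miv = _diode(p_la - p_lv, d[G_MIV], ps2)
    v_aov = _diode(p_lv - p_aor, d[G_AOV], ps2)

    # pulmonary
    v_pul = (p_par - p_pvn) * d[G_PAR]
    v_pvn = (p_pvn - p_la) * d[G_PVN]

    # arterial segments
    v_ubr = (p_aor - p_ubr) * d[G_AOR_UBR]
    v_dao = (p_aor - p_dao) * d[G_AOR_DAO]
    v_cer = (p_ubr - p_cer) * d[G_UBR_CER]
    v_bra = (p_ubr - p_bra) * d[G_UBR_BRA]
    v_mca = (p_cer - p_mca) * d[G_CER_MCA]

    # terminal inflows
    v_le = (p_dao - p_le) * d[G_LE_T]
    v_br = (p_bra - p_br) * d[G_BR_T]
    v_ac = (p_cer - p_ac) * d[G_AC_T]
    v_ec = (p_cer - p_ec) * d[G_EC_T]
    v_mc = (p_mca - p_mc) * d[G_MC_T]
    v_pc = (p_cer - p_pc) * d[G_PC_T]
    v_tr = (p_dao - p_tr) * d[G_TR_T]

    # terminal outflows into veins
    o_le = (p_le - p_vlb) * d[G_LE_V]
    o_br = (p_br - p_vub) * d[G_BR_V]
    o_ac = (p_ac - p_vub) * d[G_AC_V]
    o_ec = (p_ec - p_vub) * d[G_EC_V]
    o_mc = (p_mc - p_vub) * d[G_MC_V]
    o_pc = (p_pc - p_vub) * d[G_PC_V]
    o_tr = (p_tr - p_vlb) * d[G_TR_V]

    # venous return
    v_svc = (p_vub - p_ra) * d[G_SVC]
    v_ivc = (p_vlb - p_ra) * d[G_IVC]

    dx[X_RA] = v_svc + v_ivc - v_trv
    dx[X_RV] = v_trv - v_puv
    dx[X_LA] = v_pvn - v_miv
    dx[X_LV] = v_miv - v_aov
    dx[X_PAR] = v_puv - v_pul
    dx[X_PVN] = v_pul - v_pvn
    dx[X_AOR] = v_aov - v_ubr - v_dao
    dx[X_UBR] = v_ubr - v_cer - v_bra
    dx[X_CER] = v_cer - v_mca - v_ac - v_ec - v_pc
    dx[X_MCA] = v_mca - v_mc
    dx[X_BRA] = v_bra - v_br
    dx[X_DAO] = v_dao - v_le - v_tr
    dx[X_LE] = v_le - o_le
    dx[X_BR] = v_br - o_br
    dx[X_AC] = v_ac - o_ac
    dx[X_EC] = v_ec - o_ec
    dx[X_MC] = v_mc - o_mc
    dx[X_PC] = v_pc - o_pc
    dx[X_TR] = v_tr - o_tr
    dx[X_VUB] = o_br + o_ac + o_ec + o_mc + o_pc - v_svc
    dx[X_VLB] = o_le + o_tr - v_ivc


@njit(cache=True)
def integrate(x0, p, dt, steps_per_cycle, max_cycles, per_tol, out_every):
    """Integrate over repeated cardiac cycles until periodic.

    Returns (out, n_cycles, converged, ok).  ``out`` holds the final
    cycle's states sampled every ``out_every`` steps, including both the
    cycle-start and cycle-end points.  ``per_tol`` <= 0 disables the
    periodicity stop so exactly ``max_cycles`` cycles are run (used for
    deterministic finite-difference sensitivities).
    """
    n = x0.shape[0]
    n_out = steps_per_cycle // out_every + 1
    out = np.empty((n_out, n))
    d = derive(p)
    x = x0.copy()
    x_start = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    xt = np.empty(n)

    period = p[I_T]
    converged = False
    ok = True
    cycles_run = 0
    for cyc in range(max_cycles):
        for i in range(n):
            x_start[i] = x[i]
        out[0, :] = x
        t0 = cyc * period
        for s in range(steps_per_cycle):
            t = t0 + s * dt
            rhs(t, x, p, d, k1)
            for i in range(n):
                xt[i] = x[i] + 0.5 * dt * k1[i]
            rhs(t + 0.5 * dt, xt, p, d, k2)
            for i in range(n):
                xt[i] = x[i] + 0.5 * dt * k2[i]
            rhs(t + 0.5 * dt, xt, p, d, k3)
            for i in range(n):
                xt[i] = x[i] + dt * k3[i]
            rhs(t + dt, xt, p, d, k4)
            for i in range(n):
                x[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            if (s + 1) % out_every == 0:
                out[(s + 1) // out_every, :] = x
        cycles_run = cyc + 1

        scale = 0.0
        diff = 0.0
        finite = True
        for i in range(n):
            if not np.isfinite(x[i]):
                finite = False
            a = abs(x_start[i])
            if a > scale:
                scale = a
            dd = abs(x[i] - x_start[i])
            if dd > diff:
                diff = dd
        if not finite or scale > 1e6:
            ok = False
            break
        if per_tol > 0.0 and cyc >= 1 and diff < per_tol * (scale + 1e-300):
            converged = True
            break

    return out, cycles_run, converged, ok
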