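"""Numerical core of the two-compartment motoneuron model.

The soma carries five active currents (fast Na+, delayed-rectifier K+,
Ca2+-dependent K+, persistent Na+, N-type Ca2+ with a Nernstian calcium
reversal) and the lumped dendrite carries an L-type Ca2+ current (the
persistent inward current, PIC) plus an optional Ca2+-dependent K+ current.
The compartments are coupled by a single conductance.  Kinetic constants
(half-activation voltages, slopes, time constants) are data carried in the
parameter vector, not code, so presets fully determine the kinetics.

All rate functions are first-order sigmoids x_inf(V) = 1/(1+exp((Vh-V)/k))
with voltage-dependent time constants for the fast Na+ inactivation and the
delayed rectifier (double-exponential forms) and fixed time constants for
the Ca2+ channels.  Integration is fixed-step 4th-order Runge-Kutta.

Parameter-vector layout (``P``); conductances mS/cm2, capacitances uF/cm2,
voltages mV, areas cm2, times ms:
"""

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# parameter indices
G_M_S, G_M_D, G_C, C_M_S, C_M_D = 0, 1, 2, 3, 4
G_NAF_S, F_S, G_CAL_D, G_KCA_D, S_NM = 5, 6, 7, 8, 9
G_KDR_S, G_KCA_S, G_NAP_S, G_CAN_S = 10, 11, 12, 13
E_LEAK, E_NA, E_K, E_CA_D, CA_OUT = 14, 15, 16, 17, 18
A_S, A_D = 19, 20
ALPHA_CA, K_CA, F_D, KD_KCA = 21, 22, 23, 24
E_ESYN, E_ISYN = 25, 26
VH_NAF_M, K_NAF_M, VH_NAF_H, K_NAF_H = 27, 28, 29, 30
VH_KDR, K_KDR = 31, 32
VH_CAN_M, K_CAN_M, VH_CAN_H, K_CAN_H = 33, 34, 35, 36
TAU_CAN_M, TAU_CAN_H = 37, 38
VH_NAP, K_NAP = 39, 40
VH_CAL, K_CAL, TAU_CAL = 41, 42, 43
CA_REST = 44

N_PARAMS = 45

# state indices: V_S, V_D, h_naf, n_kdr, m_can, h_can, l_cal, Ca_S, Ca_D
N_STATES = 9

# Nernst prefactor RT/2F at body temperature (mV).
_NERNST_CA = 13.27


@njit(cache=True, fastmath=False)
def _sig(v, vh, k):
    return 1.0 / (1.0 + np.exp((vh - v) / k))


@njit(cache=True, fastmath=False)
def mn_rhs(y, P, i_soma_na, g_e, g_i, dydt):
    """State derivative; synaptic conductances act on the dendrite."""
    v_s, v_d = y[0], y[1]
    h, n, mc, hc, l = y[2], y[3], y[4], y[5], y[6]
    ca_s, ca_d = max(y[7], 0.0), max(y[8], 0.0)
    # voltages entering rate functions are clamped so exp() cannot overflow
    # while a diverging trajectory is being detected by the caller
    vr_s = min(max(v_s, -150.0), 150.0)
    vr_d = min(max(v_d, -150.0), 150.0)

    p = P[A_S] / (P[A_S] + P[A_D])

    # --- soma (current densities, uA/cm2)
    m_inf = _sig(vr_s, P[VH_NAF_M], P[K_NAF_M])
    i_naf = P[G_NAF_S] * m_inf ** 3 * h * (v_s - P[E_NA])
    i_kdr = P[G_KDR_S] * n ** 4 * (v_s - P[E_K])
    e_ca_s = _NERNST_CA * np.log(P[CA_OUT] / max(ca_s, 1e-8))
    i_can = P[G_CAN_S] * mc * mc * hc * (v_s - e_ca_s)
    i_kca_s = P[G_KCA_S] * ca_s / (ca_s + P[KD_KCA]) * (v_s - P[E_K])
    i_nap = P[G_NAP_S] * _sig(vr_s, P[VH_NAP], P[K_NAP]) * (v_s - P[E_NA])
    i_leak_s = P[G_M_S] * (v_s - P[E_LEAK])
    i_cpl_s = (P[G_C] / p) * (v_s - v_d)
    i_inj = i_soma_na * 1e-3 / P[A_S]
    dydt[0] = (-i_leak_s - i_naf - i_kdr - i_kca_s - i_nap - i_can
               - i_cpl_s + i_inj) / P[C_M_S]

    # --- dendrite
    i_cal = P[S_NM] * P[G_CAL_D] * l * (v_d - P[E_CA_D])
    i_kca_d = P[G_KCA_D] * ca_d / (ca_d + P[KD_KCA]) * (v_d - P[E_K])
    i_syn = g_e * (v_d - P[E_ESYN]) + g_i * (v_d - P[E_ISYN])
    i_leak_d = P[G_M_D] * (v_d - P[E_LEAK])
    i_cpl_d = (P[G_C] / (1.0 - p)) * (v_d - v_s)
    dydt[1] = (-i_leak_d - i_cal - i_kca_d - i_syn - i_cpl_d) / P[C_M_D]

    # --- gating
    h_inf = _sig(vr_s, P[VH_NAF_H], -P[K_NAF_H])
    tau_h = 30.0 / (np.exp((vr_s + 50.0) / 15.0) + np.exp(-(vr_s + 50.0) / 16.0))
    dydt[2] = (h_inf - h) / tau_h

    n_inf = _sig(vr_s, P[VH_KDR], P[K_KDR])
    tau_n = 7.0 / (np.exp((vr_s + 40.0) / 40.0) + np.exp(-(vr_s + 40.0) / 50.0))
    dydt[3] = (n_inf - n) / tau_n

    dydt[4] = (_sig(vr_s, P[VH_CAN_M], P[K_CAN_M]) - mc) / P[TAU_CAN_M]
    dydt[5] = (_sig(vr_s, P[VH_CAN_H], -P[K_CAN_H]) - hc) / P[TAU_CAN_H]
    dydt[6] = (_sig(vr_d, P[VH_CAL], P[K_CAL]) - l) / P[TAU_CAL]

    # --- calcium (model-internal concentration units; removal relaxes the
    # free concentration back to its resting level)
    dydt[7] = P[F_S] * (-P[ALPHA_CA] * i_can - P[K_CA] * (ca_s - P[CA_REST]))
    dydt[8] = P[F_D] * (-P[ALPHA_CA] * i_cal - P[K_CA] * (ca_d - P[CA_REST]))


@njit(cache=True)
def integrate_mn(P, y0, i_soma, g_e, g_i, dt, substeps=2):
    """Fixed-step RK4; inputs are per-step sample-and-hold arrays.

    ``substeps`` internal RK4 steps are taken per recorded sample so the
    sodium upstroke stays well resolved while the output grid (and the
    sample-and-hold inputs) remain at ``dt``.

    Returns (V_S series, V_D series, final state).  Raises no exceptions
    inside the jitted loop; divergence is detected by the caller from the
    returned trace.
    """
    n = i_soma.shape[0]
    h_dt = dt / substeps
    vs = np.empty(n)
    vd = np.empty(n)
    y = y0.copy()
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    yt = np.empty(N_STATES)
    vs[0] = y[0]
    vd[0] = y[1]
    for i in range(n - 1):
        ii, ge, gi = i_soma[i], g_e[i], g_i[i]
        for _ in range(substeps):
            mn_rhs(y, P, ii, ge, gi, k1)
            for j in range(N_STATES):
                yt[j] = y[j] + 0.5 * h_dt * k1[j]
            mn_rhs(yt, P, ii, ge, gi, k2)
            for j in range(N_STATES):
                yt[j] = y[j] + 0.5 * h_dt * k2[j]
            mn_rhs(yt, P, ii, ge, gi, k3)
            for j in range(N_STATES):
                yt[j] = y[j] + h_dt * k3[j]
            mn_rhs(yt, P, ii, ge, gi, k4)
            for j in range(N_STATES):
                y[j] += h_dt * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
            # clip gating to [0,1] and calcium to >= 0 against round-off
            for j in range(2, 7):
                if y[j] < 0.0:
                    y[j] = 0.0
                elif y[j] > 1.0:
                    y[j] = 1.0
            if y[7] < 0.0:
                y[7] = 0.0
            if y[8] < 0.0:
                y[8] = 0.0
        vs[i + 1] = y[0]
        vd[i + 1] = y[1]
        if not np.isfinite(y[0]) or abs(y[0]) > 500.0:
            for kk in range(i + 2, n):
                vs[kk] = np.nan
                vd[kk] = np.nan
            break
    return vs, vd, y


@njit(cache=True)
def integrate_mn_clamped(P, y0, v_cmd, g_e, g_i, dt):
    """Somatic voltage clamp: V_S is substituted algebraically by ``v_cmd``.

    The dendrite and all gating/calcium states evolve freely.  Returns the
    clamp current (nA, outward positive) needed to hold the command,
    including the capacitive component, plus the dendritic voltage series.
    """
    n = v_cmd.shape[0]
    i_clamp = np.empty(n)
    vd = np.empty(n)
    y = y0.copy()
    k1 = np.empty(N_STATES)
    k2 = np.empty(N_STATES)
    k3 = np.empty(N_STATES)
    k4 = np.empty(N_STATES)
    yt = np.empty(N_STATES)
    p = P[A_S] / (P[A_S] + P[A_D])
    for i in range(n):
        y[0] = v_cmd[i]
        v_s = y[0]
        # somatic membrane + coupling current at the held potential
        m_inf = _sig(v_s, P[VH_NAF_M], P[K_NAF_M])
        i_naf = P[G_NAF_S] * m_inf ** 3 * y[2] * (v_s - P[E_NA])
        i_kdr = P[G_KDR_S] * y[3] ** 4 * (v_s - P[E_K])
        ca_s = max(y[7], 1e-8)
        e_ca_s = _NERNST_CA * np.log(P[CA_OUT] / ca_s)
        i_can = P[G_CAN_S] * y[4] * y[4] * y[5] * (v_s - e_ca_s)
        i_kca_s = P[G_KCA_S] * ca_s / (ca_s + P[KD_KCA]) * (v_s - P[E_K])
        i_nap = P[G_NAP_S] * _sig(v_s, P[VH_NAP], P[K_NAP]) * (v_s - P[E_NA])
        i_leak_s = P[G_M_S] * (v_s - P[E_LEAK])
        i_cpl_s = (P[G_C] / p) * (v_s - y[1])
        dvdt = (v_cmd[min(i + 1, n - 1)] - v_cmd[i]) / dt
        dens = (i_leak_s + i_naf + i_kdr + i_kca_s + i_nap + i_can
                + i_cpl_s + P[C_M_S] * dvdt)
        i_clamp[i] = dens * P[A_S] * 1e3  # uA/cm2 * cm2 -> uA -> nA(*1e3)
        vd[i] = y[1]
        if i == n - 1:
            break
        ge, gi = g_e[i], g_i[i]
        mn_rhs(y, P, 0.0, ge, gi, k1)
        k1[0] = 0.0
        for j in range(N_STATES):
            yt[j] = y[j] + 0.5 * dt * k1[j]
        yt[0] = v_cmd[i]
        mn_rhs(yt, P, 0.0, ge, gi, k2)
        k2[0] = 0.0
        for j in range(N_STATES):
            yt[j] = y[j] + 0.5 * dt * k2[j]
        yt[0] = v_cmd[i]
        mn_rhs(yt, P, 0.0, ge, gi, k3)
        k3[0] = 0.0
        for j in range(N_STATES):
            yt[j] = y[j] + dt * k3[j]
        yt[0] = v_cmd[i + 1]
        mn_rhs(yt, P, 0.0, ge, gi, k4)
        k4[0] = 0.0
        for j in range(N_STATES):
            y[j] += dt * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j]) / 6.0
        for j in range(2, 7):
            if y[j] < 0.0:
                y[j] = 0.0
            elif y[j] > 1.0:
                y[j] = 1.0
        if y[7] < 0.0:
            y[7] = 0.0
        if y[8] < 0.0:
            y[8] = 0.0
    return i_clamp, vd
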