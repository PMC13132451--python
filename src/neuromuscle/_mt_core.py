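"""Numerical core of the three-module muscle-tendon fiber model.

Module 1 turns the axonal spike train into a free-calcium signal: each
spike launches a two-exponential release transient (rise tau_1, fall
tau_2), linearly superposed, with its amplitude scaled by a
length-dependence factor (unity at the intermediate length, falling at
rate phi_1 below it, rising at rate phi_3 above it).

Module 2 maps calcium to activation through a Hill-type sigmoid whose
half-point c1(t) and steepness c2(t) relax from their initial values
toward saturation limits while calcium is elevated (this produces the
slow/fast differences in unfused tetani, including "sag"), attenuated
under fluctuating calcium (alpha_i) and by movement (beta, gamma).

Module 3 is Hill mechanics: a contractile element (force-length Gaussian,
force-velocity Hill/Mashima branches) in series with a linear elastic
element clipped at zero when slack.  The contractile velocity is obtained
by closed-form inversion of the force-velocity relation at the current
force ratio.

Parameter-vector layout in ``P`` (times ms, lengths mm, velocities mm/s,
forces N):
"""

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

TAU_1, TAU_2, PHI_1, PHI_3 = 0, 1, 2, 3
C1I, C1N1, C1N4, C2I, C2N1, C2N4, ALPHA_I = 4, 5, 6, 7, 8, 9, 10
BETA, GAMMA = 11, 12
P0_5, G_1, G_2, A_0, B_0, C_0, D_0, K_SE = 13, 14, 15, 16, 17, 18, 19, 20
A_MUAP, L_MUAP = 21, 22
X_HALF, CA_NORM, TAU_FLUCT, V_CAP, P0_SCALE, CA_SAT = 23, 24, 25, 26, 27, 28

N_PARAMS = 29

# state: y1, y2 (release), c1, c2, ca_bar, x_ce
N_STATES = 6


@njit(cache=True)
def fl_gauss(x_ce, g_1, g_2):
    u = (x_ce - g_1) / g_2
    return np.exp(-u * u)


@njit(cache=True)
def fv_forward(v_ce, a_0, b_0, c_0, d_0):
    """Normalized force-velocity factor; v_ce > 0 is lengthening."""
    if v_ce < 0.0:
        s = -v_ce
        if s >= b_0 / a_0:
            return 0.0
        return (b_0 - a_0 * s) / (b_0 + s)
    return (c_0 + d_0 * v_ce) / (c_0 + v_ce)


@njit(cache=True)
def fv_invert(r, a_0, b_0, c_0, d_0, v_cap):
    """Contractile velocity at force ratio ``r`` (mm/s; > 0 lengthening).

    The lengthening branch saturates at d_0; ratios at/above it are capped
    at ``v_cap`` (the free-lengthening regime of a nearly inactive fiber).
    """
    if r < 0.0:
        r = 0.0
    if r < 1.0:
        return -b_0 * (1.0 - r) / (r + a_0)
    if r >= d_0:
        return v_cap
    v = c_0 * (r - 1.0) / (d_0 - r)
    if v > v_cap:
        return v_cap
    return v


@njit(cache=True)
def integrate_mt(P, spike_steps, x_m, dt):
    """Run the three modules on the shared grid.

    ``spike_steps``: sorted sample indices at which stimulation impulses
    arrive.  Returns (force, activation, x_ce, ca) series.
    """
    n = x_m.shape[0]
    force = np.zeros(n)
    act = np.zeros(n)
    xce = np.empty(n)
    ca_out = np.zeros(n)

    d1 = np.exp(-dt / P[TAU_1])
    d2 = np.exp(-dt / P[TAU_2])
    dfl = np.exp(-dt / P[TAU_FLUCT])

    y1 = 0.0
    y2 = 0.0
    c1 = P[C1I]
    c2 = P[C2I]
    ca_bar = 0.0
    # start with the series-elastic element just slack
    x_ce = x_m[0]
    v_ce = 0.0

    isp = 0
    n_sp = spike_steps.shape[0]
    x_ref = x_m[0]

    for i in range(n):
        # module 1: impulse responses, amplitude scaled by the length factor
        while isp < n_sp and spike_steps[isp] == i:
            xm = x_m[i]
            if xm < P[X_HALF]:
                fac = np.exp(P[PHI_1] * (xm - P[X_HALF]))
            else:
                fac = np.exp(P[PHI_3] * (xm - P[X_HALF]))
            y1 += fac
            y2 += fac
            isp += 1
        ca = (y2 - y1) / P[CA_NORM]
        if ca < 0.0:
            ca = 0.0
        ca_out[i] = ca

        # module 2: dynamic calcium-force relation
        u = ca / P[CA_SAT]
        if u > 1.0:
            u = 1.0
        c1_t = P[C1I] + (P[C1N1] - P[C1I]) * u
        c2_t = P[C2I] + (P[C2N1] - P[C2I]) * u
        c1 += (1.0 - np.exp(-dt / P[C1N4])) * (c1_t - c1)
        c2 += (1.0 - np.exp(-dt / P[C2N4])) * (c2_t - c2)
        ca_bar += (1.0 - dfl) * (ca - ca_bar)
        if ca > 0.0:
            a_sig = ca ** c2 / (ca ** c2 + c1 ** c2)
        else:
            a_sig = 0.0
        fluct = abs(ca - ca_bar) / (ca_bar + 0.1)
        d_fl = 1.0 / (1.0 + P[ALPHA_I] * fluct)
        mov = 1.0 - P[BETA] * abs(x_ce - x_ref) - P[GAMMA] * abs(v_ce) * 1e-3
        if mov < 0.0:
            mov = 0.0
        a = a_sig * d_fl * mov
        if a > 1.0:
            a = 1.0
        act[i] = a

        # module 3: Hill mechanics with series elasticity
        stretch = x_m[i] - x_ce
        f_se = P[K_SE] * stretch if stretch > 0.0 else 0.0
        force[i] = f_se
        xce[i] = x_ce
        denom = P[P0_SCALE] * a * fl_gauss(x_ce, P[G_1], P[G_2])
        if denom > 1e-9:
            r = f_se / denom
            v_ce = fv_invert(r, P[A_0], P[B_0], P[C_0], P[D_0], P[V_CAP])
        else:
            # inactive fiber: the contractile element follows the imposed
            # length so the series element stays slack
            v_ce = (x_m[i] - x_ce) / dt * 1e3 if stretch > 0.0 else 0.0
            if v_ce > P[V_CAP]:
                v_ce = P[V_CAP]
        x_ce += v_ce * 1e-3 * dt  # mm/s * ms
        # advance module-1 states to the next sample
        y1 *= d1
        y2 *= d2

    return force, act, xce, ca_out
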