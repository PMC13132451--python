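"""Three-module muscle-tendon fiber: calcium release, activation dynamics,
Hill mechanics, and action-potential (MUAP) synthesis.

Lengths are muscle-tendon lengths X_m in mm with 0 at the physiological
maximum; the intermediate length X_m,0.5 is -8 mm.  Forces are in N.  The
contractile-element maximal force is calibrated at construction so that the
fully excited isometric force at the intermediate length equals the
parameter P_0.5 (which is therefore an observable, not a raw gain).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import _mt_core as core
from . import config
from .signals import Signal, SpikeTrain


@dataclass
class MuscleTendonRMP:
    """Cell-varying parameters of the three modules (see Table of fields)."""

    tau_1: float          # Ca release rise time constant (ms)
    tau_2: float          # Ca release fall time constant (ms)
    phi_1: float          # activation decrease rate below X_m,0.5 (1/mm)
    phi_3: float          # activation increase rate above X_m,0.5 (1/mm)
    c1i: float            # initial half-activation Ca concentration
    c1n1: float           # saturation limit of c1
    c1n4: float           # time constant of c1 dynamics (ms)
    c2i: float            # initial steepness of the Ca-force sigmoid
    c2n1: float           # saturation limit of c2
    c2n4: float           # time constant of c2 dynamics (ms)
    alpha_i: float        # activation degradation under fluctuating Ca
    beta: float           # length coefficient of movement degradation (1/mm)
    gamma: float          # velocity coefficient (per mm/s)
    p0_5: float           # peak isometric force at the intermediate length (N)
    g_1: float            # CE length of the force-length peak (mm)
    g_2: float            # width of the force-length curve (mm)
    a_0: float            # Hill shortening coefficient (dimensionless)
    b_0: float            # Hill shortening coefficient (mm/s)
    c_0: float            # Mashima lengthening coefficient (mm/s)
    d_0: float            # Mashima lengthening asymptote (dimensionless)
    k_se: float           # series elastic stiffness (N/mm)
    a_muap: float = 0.3   # MUAP amplitude (mV)
    l_muap: float = 10.0  # MUAP duration (ms)

    def validate(self) -> None:
        for name in ("tau_1", "tau_2", "c1n4", "c2n4", "g_2", "k_se",
                     "l_muap", "p0_5"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("phi_1", "phi_3", "alpha_i", "beta", "gamma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.tau_1 == self.tau_2:
            raise ValueError("tau_1 must differ from tau_2 (degenerate kernel)")
        if self.d_0 <= 1.0:
            raise ValueError("lengthening asymptote d_0 must exceed 1")


@dataclass
class MuscleTendonCMP:
    """Population-constant numerical choices of the fiber model."""

    x_half: float = config.XM_INTERMEDIATE_MM  # intermediate length (mm)
    tau_fluct: float = 150.0   # Ca low-pass for the fluctuation index (ms)
    v_cap: float = 1000.0      # velocity cap in the inactive regime (mm/s)
    ca_sat: float = 1.0        # Ca level treated as saturating for c1/c2 drive


@dataclass
class MTTrace:
    """Simulated fiber response on the shared grid."""

    dt: float
    force: np.ndarray      # N
    x_ce: np.ndarray       # mm
    activation: np.ndarray
    ca: np.ndarray
    muap: np.ndarray       # mV

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.force.size)


def ca_kernel_norm(tau_1: float, tau_2: float) -> float:
    """Peak value of exp(-t/tau_2) - exp(-t/tau_1) (closed form)."""
    r = tau_1 / tau_2
    e = tau_1 / (tau_2 - tau_1)
    return r ** e - r ** (e + 1.0)


def ca_peak_time(tau_1: float, tau_2: float) -> float:
    """Time of the release-transient peak: ln(tau_2/tau_1)*tau_1*tau_2/(tau_2-tau_1)."""
    return np.log(tau_2 / tau_1) * tau_1 * tau_2 / (tau_2 - tau_1)


def p0_scale(rmp: MuscleTendonRMP,
             cmp: MuscleTendonCMP | None = None) -> float:
    """Maximal CE force such that the fully excited isometric force at the
    intermediate length equals P_0.5 (closed-form calibration: the SE
    stretch at that force is P_0.5/K_SE)."""
    cmp = cmp or MuscleTendonCMP()
    x_eq = cmp.x_half - rmp.p0_5 / rmp.k_se
    return rmp.p0_5 / fl_factor(x_eq, rmp.g_1, rmp.g_2)


def pack_params(rmp: MuscleTendonRMP,
                cmp: MuscleTendonCMP | None = None) -> np.ndarray:
    cmp = cmp or MuscleTendonCMP()
    rmp.validate()
    P = np.zeros(core.N_PARAMS)
    P[core.TAU_1], P[core.TAU_2] = rmp.tau_1, rmp.tau_2
    P[core.PHI_1], P[core.PHI_3] = rmp.phi_1, rmp.phi_3
    P[core.C1I], P[core.C1N1], P[core.C1N4] = rmp.c1i, rmp.c1n1, rmp.c1n4
    P[core.C2I], P[core.C2N1], P[core.C2N4] = rmp.c2i, rmp.c2n1, rmp.c2n4
    P[core.ALPHA_I], P[core.BETA], P[core.GAMMA] = (rmp.alpha_i, rmp.beta,
                                                    rmp.gamma)
    P[core.P0_5], P[core.G_1], P[core.G_2] = rmp.p0_5, rmp.g_1, rmp.g_2
    P[core.A_0], P[core.B_0] = rmp.a_0, rmp.b_0
    P[core.C_0], P[core.D_0] = rmp.c_0, rmp.d_0
    P[core.K_SE] = rmp.k_se
    P[core.A_MUAP], P[core.L_MUAP] = rmp.a_muap, rmp.l_muap
    P[core.X_HALF] = cmp.x_half
    P[core.CA_NORM] = ca_kernel_norm(rmp.tau_1, rmp.tau_2)
    P[core.TAU_FLUCT] = cmp.tau_fluct
    P[core.V_CAP] = cmp.v_cap
    P[core.P0_SCALE] = p0_scale(rmp, cmp)
    P[core.CA_SAT] = cmp.ca_sat
    return P


# ---------------------------------------------------------------------------
# module-level functions (exposed for testing and inversion)


def calcium_release(spikes: SpikeTrain, tau_1: float, tau_2: float,
                    phi_1: float = 0.0, phi_3: float = 0.0,
                    x_m: Signal | None = None, dt_ms: float = config.DT_MS,
                    T_ms: float | None = None) -> Signal:
    """Free-calcium signal: superposed two-exponential release transients.

    A single transient at the intermediate length peaks at 1 at time
    ``ca_peak_time(tau_1, tau_2)`` after the spike.
    """
    if tau_1 == tau_2:
        raise ValueError("tau_1 must differ from tau_2 (degenerate kernel)")
    if T_ms is None:
        T_ms = (x_m.duration if x_m is not None else
                (spikes.spike_times[-1] + 5 * tau_2 if len(spikes) else 100.0))
    n = int(round(T_ms / dt_ms)) + 1
    t = dt_ms * np.arange(n)
    norm = ca_kernel_norm(tau_1, tau_2)
    x_half = config.XM_INTERMEDIATE_MM
    ca = np.zeros(n)
    for ts in spikes.spike_times:
        if ts > T_ms:
            break
        xm = x_m.at(ts) if x_m is not None else x_half
        rate = phi_1 if xm < x_half else phi_3
        fac = np.exp(rate * (xm - x_half))
        tau = t[t >= ts] - ts
        ca[t >= ts] += fac * (np.exp(-tau / tau_2) - np.exp(-tau / tau_1)) / norm
    return Signal(0.0, dt_ms, np.maximum(ca, 0.0))


def fl_factor(x_ce, g_1: float, g_2: float):
    """Gaussian force-length factor, peak 1 at ``g_1``, width set by ``g_2``."""
    if g_2 <= 0:
        raise ValueError("g_2 must be positive")
    u = (np.asarray(x_ce, dtype=float) - g_1) / g_2
    out = np.exp(-u * u)
    return float(out) if np.isscalar(x_ce) else out


def fv_factor(v_ce, a_0: float, b_0: float, c_0: float, d_0: float):
    """Force-velocity factor: Hill hyperbola for shortening (v < 0),
    Mashima form for lengthening (v > 0); fv(0) = 1 by construction."""
    v = np.atleast_1d(np.asarray(v_ce, dtype=float))
    out = np.empty_like(v)
    for i, vi in enumerate(v):
        out[i] = core.fv_forward(vi, a_0, b_0, c_0, d_0)
    return float(out[0]) if np.isscalar(v_ce) else out


def activation_dynamics(ca: Signal, rmp: MuscleTendonRMP,
                        x_ce: np.ndarray | None = None,
                        v_ce: np.ndarray | None = None,
                        cmp: MuscleTendonCMP | None = None) -> np.ndarray:
    """Module-2 mapping from a calcium series to activation in [0, 1].

    With beta = gamma = 0 the result is independent of the mechanical
    inputs (no spurious coupling of modules 2 and 3).
    """
    cmp = cmp or MuscleTendonCMP()
    cav = ca.values
    if np.any(cav < 0):
        raise ValueError("calcium input must be non-negative")
    n = cav.size
    dt = ca.dt
    if x_ce is None:
        x_ce = np.zeros(n)
    if v_ce is None:
        v_ce = np.zeros(n)
    c1, c2, ca_bar = rmp.c1i, rmp.c2i, 0.0
    e1 = 1.0 - np.exp(-dt / rmp.c1n4)
    e2 = 1.0 - np.exp(-dt / rmp.c2n4)
    efl = 1.0 - np.exp(-dt / cmp.tau_fluct)
    out = np.empty(n)
    x_ref = x_ce[0]
    for i in range(n):
        u = min(cav[i] / cmp.ca_sat, 1.0)
        c1 += e1 * (rmp.c1i + (rmp.c1n1 - rmp.c1i) * u - c1)
        c2 += e2 * (rmp.c2i + (rmp.c2n1 - rmp.c2i) * u - c2)
        ca_bar += efl * (cav[i] - ca_bar)
        a_sig = (cav[i] ** c2 / (cav[i] ** c2 + c1 ** c2)
                 if cav[i] > 0 else 0.0)
        fluct = abs(cav[i] - ca_bar) / (ca_bar + 0.1)
        d_fl = 1.0 / (1.0 + rmp.alpha_i * fluct)
        mov = max(0.0, 1.0 - rmp.beta * abs(x_ce[i] - x_ref)
                  - rmp.gamma * abs(v_ce[i]) * 1e-3)
        out[i] = min(a_sig * d_fl * mov, 1.0)
    return out


def hill_equilibrium(a: float, x_m: float, rmp: MuscleTendonRMP,
                     cmp: MuscleTendonCMP | None = None) -> tuple[float, float]:
    """Isometric fixed point (F, X_CE) at activation ``a`` by root-finding
    the force balance K_SE (X_m - X_CE) = scale * a * fl(X_CE)."""
    from scipy.optimize import brentq
    cmp = cmp or MuscleTendonCMP()
    scale = p0_scale(rmp, cmp)

    def bal(x):
        return rmp.k_se * (x_m - x) - scale * a * fl_factor(x, rmp.g_1, rmp.g_2)

    if a <= 0 or bal(x_m) >= 0:
        return 0.0, x_m
    lo = x_m - scale * a / rmp.k_se - 1.0
    x_eq = brentq(bal, lo, x_m, xtol=1e-10)
    return rmp.k_se * (x_m - x_eq), x_eq


def hill_step(a: float, x_m: float, x_ce: float, rmp: MuscleTendonRMP,
              dt_ms: float, cmp: MuscleTendonCMP | None = None
              ) -> tuple[float, float, float]:
    """One mechanics step: returns (force, new X_CE, V_CE)."""
    if not (0.0 <= a <= 1.0):
        raise ValueError("activation must lie in [0, 1]")
    cmp = cmp or MuscleTendonCMP()
    stretch = x_m - x_ce
    f_se = rmp.k_se * stretch if stretch > 0 else 0.0
    denom = p0_scale(rmp, cmp) * a * fl_factor(x_ce, rmp.g_1, rmp.g_2)
    if denom > 1e-9:
        v_ce = core.fv_invert(f_se / denom, rmp.a_0, rmp.b_0, rmp.c_0,
                              rmp.d_0, cmp.v_cap)
    else:
        v_ce = min((x_m - x_ce) / dt_ms * 1e3, cmp.v_cap) if stretch > 0 else 0.0
    return f_se, x_ce + v_ce * 1e-3 * dt_ms, v_ce


def muap_waveform(dt_ms: float, a_muap: float, l_muap: float) -> np.ndarray:
    """First-order Hermite-Rodriguez biphasic waveform of support
    ``l_muap`` ms, scaled to peak amplitude ``a_muap`` mV; zero-mean by
    antisymmetry."""
    if l_muap <= 0:
        raise ValueError("l_muap must be positive")
    lam = l_muap / 6.0
    t = dt_ms * np.arange(int(round(l_muap / dt_ms)) + 1) - l_muap / 2.0
    u = t / lam
    w = u * np.exp(-u * u)
    return a_muap * w / np.abs(w).max()


def muap_train(spikes: SpikeTrain, delay_ms: float, a_muap: float,
               l_muap: float, dt_ms: float, T_ms: float) -> Signal:
    """Linear superposition of one stereotyped MUAP per spike, shifted by
    the conduction delay."""
    n = int(round(T_ms / dt_ms)) + 1
    out = np.zeros(n)
    w = muap_waveform(dt_ms, a_muap, l_muap)
    for ts in spikes.spike_times:
        i0 = int(round((ts + delay_ms) / dt_ms))
        if i0 >= n:
            continue
        i1 = min(i0 + w.size, n)
        if i0 < 0:
            continue
        out[i0:i1] += w[: i1 - i0]
    return Signal(0.0, dt_ms, out)


def simulate_mt(rmp: MuscleTendonRMP, spikes: SpikeTrain,
                x_m: Signal | None = None, dt_ms: float = config.DT_MS,
                T_ms: float | None = None,
                cmp: MuscleTendonCMP | None = None,
                muap_delay_ms: float = 0.0) -> MTTrace:
    """Chain modules 1 -> 2 -> 3 on the shared grid and synthesize the MUAP
    train (delayed by ``muap_delay_ms``, normally the axonal conduction
    delay applied upstream)."""
    cmp = cmp or MuscleTendonCMP()
    if T_ms is None:
        if x_m is not None:
            T_ms = x_m.duration
        elif len(spikes):
            T_ms = spikes.spike_times[-1] + 10 * rmp.tau_2
        else:
            T_ms = 100.0
    n = int(round(T_ms / dt_ms)) + 1
    xm = (x_m.resampled_to(dt_ms, T_ms).values if x_m is not None
          else np.full(n, cmp.x_half))
    P = pack_params(rmp, cmp)
    steps = np.asarray(np.round(spikes.spike_times / dt_ms), dtype=np.int64)
    steps = steps[steps < n]
    force, act, xce, ca = core.integrate_mt(P, steps, xm, dt_ms)
    muap = muap_train(spikes, muap_delay_ms, rmp.a_muap, rmp.l_muap,
                      dt_ms, T_ms)
    return MTTrace(dt_ms, force, xce, act, ca, muap.values)


# ---------------------------------------------------------------------------
# twitch / tetanus summary measures (inversion targets)


def twitch_metrics(rmp: MuscleTendonRMP, x_m_mm: float | None = None,
                   dt_ms: float = config.DT_MS,
                   cmp: MuscleTendonCMP | None = None
                   ) -> tuple[float, float, float]:
    """Single-twitch (peak force, contraction time, half-relaxation time)
    under isometric conditions."""
    cmp = cmp or MuscleTendonCMP()
    if x_m_mm is None:
        x_m_mm = cmp.x_half
    T = 2000.0
    tr = simulate_mt(rmp, SpikeTrain(np.array([10.0])),
                     x_m=Signal(0.0, dt_ms,
                                np.full(int(round(T / dt_ms)) + 1, x_m_mm)),
                     dt_ms=dt_ms, cmp=cmp)
    f = tr.force
    ipk = int(np.argmax(f))
    peak = f[ipk]
    if peak <= 0:
        raise RuntimeError("twitch produced no force")
    t_ct = tr.dt * ipk - 10.0
    below = np.flatnonzero(f[ipk:] <= 0.5 * peak)
    t_hr = tr.dt * below[0] if below.size else np.nan
    return peak, t_ct, t_hr


def tetanus_force(rmp: MuscleTendonRMP, rate_hz: float = 100.0,
                  x_m_mm: float | None = None, T_ms: float = 3000.0,
                  dt_ms: float = config.DT_MS,
                  cmp: MuscleTendonCMP | None = None) -> float:
    """Peak force of a sustained tetanus at ``rate_hz``."""
    from .signals import gen_spike_train
    cmp = cmp or MuscleTendonCMP()
    if x_m_mm is None:
        x_m_mm = cmp.x_half
    spikes = gen_spike_train(rate_hz, 10.0, T_ms - 200.0)
    tr = simulate_mt(rmp, spikes,
                     x_m=Signal(0.0, dt_ms,
                                np.full(int(round(T_ms / dt_ms)) + 1, x_m_mm)),
                     dt_ms=dt_ms, cmp=cmp)
    return float(tr.force.max())
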