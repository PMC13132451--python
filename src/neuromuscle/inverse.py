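"""Inverse parameter determination and population construction.

The forward problem (motoneuron.py, muscle_tendon.py) maps model
parameters to measurable cell properties (CPs).  This module implements
the two inverse layers:

- ``RMP = f^-1(CP)``: given a cell's measured properties, recover the
  range model parameters.  Passive motoneuron parameters invert in closed
  form from the two-node circuit; active parameters invert through
  forward-measured lookup tables refined against live simulation; the
  muscle-tendon fiber inverts stage by stage in module order (twitch
  dynamics -> length dependence -> calcium-force relation -> Hill
  mechanics -> elasticity).

- ``CP = g(CI)``: cell properties as functions of a single cell indicator
  (input resistance R_N for motoneurons and motor units, peak isometric
  force P_0.5 for fibers), expressed as named correlation curves loaded
  from CSV so experimental correlation sets are user-replaceable.

``build_population`` composes the two layers: a distribution of cell
indicators plus a correlation set yields a fully parameterized,
heterogeneous pool with a per-cell provenance record.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, root

from . import config
from . import io as nio
from . import motoneuron as mnm
from . import muscle_tendon as mtm
from .motor_unit import MotorUnitParams
from .motoneuron import MotoneuronCMP, MotoneuronRMP
from .muscle_tendon import MuscleTendonCMP, MuscleTendonRMP


# ---------------------------------------------------------------------------
# passive inversion (closed form + 1D root-find)


def invert_passive(r_n: float, tau_m: float, va_sd_dc: float,
                   va_ds_dc: float, va_sd_ac: float,
                   cmp: MotoneuronCMP) -> dict[str, float]:
    """Unique passive parameter set reproducing the five passive CPs.

    DC part in closed form: the attenuation factors fix the conductance
    ratios (g_D/g_C and g_S/g_C) and R_N fixes the scale.  The dendritic
    capacitance follows from the AC attenuation at the measurement
    frequency; the somatic capacitance is the root of the slowest-eigenvalue
    condition for tau_m.
    """
    if not (0 < va_sd_dc <= 1 and 0 < va_ds_dc <= 1):
        raise ValueError("attenuation factors must lie in (0, 1]")
    if va_sd_ac >= va_sd_dc:
        raise ValueError("infeasible CP: AC attenuation must be below DC "
                         f"({va_sd_ac} >= {va_sd_dc})")
    alpha = (1.0 - va_sd_dc) / va_sd_dc       # g_D / g_C
    beta = (1.0 - va_ds_dc) / va_ds_dc        # g_S / g_C
    denom = alpha * beta + alpha + beta
    if denom <= 0 or r_n <= 0:
        raise ValueError("infeasible CP: degenerate conductance ratios")
    g_c = (alpha + 1.0) / (r_n * denom)       # uS
    g_d = alpha * g_c
    g_s = beta * g_c

    omega = 2e-3 * np.pi * mnm.AC_FREQUENCY_HZ  # rad/ms
    c_d = np.sqrt((g_c / va_sd_ac) ** 2 - (g_c + g_d) ** 2) / omega  # nF

    def lam_min(c_s: float) -> float:
        a11 = (g_s + g_c) / c_s
        a22 = (g_d + g_c) / c_d
        a12a21 = (g_c / c_s) * (g_c / c_d)
        tr, det = a11 + a22, a11 * a22 - a12a21
        return 0.5 * (tr - np.sqrt(tr * tr - 4.0 * det))

    def f(c_s: float) -> float:
        return 1.0 / lam_min(c_s) - tau_m

    lo, hi = 1e-6, 1e3
    if f(lo) > 0 and f(hi) > 0 or f(lo) < 0 and f(hi) < 0:
        raise ValueError("infeasible CP: no somatic capacitance yields the "
                         f"requested tau_m = {tau_m}")
    c_s = brentq(f, lo, hi, xtol=1e-12)

    a_s, a_d, a_t = cmp.area_s, cmp.area_d, cmp.area_s + cmp.area_d
    return {
        "g_m_s": g_s / (a_s * 1e3),
        "g_m_d": g_d / (a_d * 1e3),
        "g_c": g_c / (a_t * 1e3),
        "c_m_s": c_s / (a_s * 1e3),
        "c_m_d": c_d / (a_d * 1e3),
    }


# ---------------------------------------------------------------------------
# lookup tables over forward measurements


@dataclass
class LookupTable:
    """Rectangular grid of RMP values with forward-measured CPs.

    ``values[i, j, k]`` is CP ``cp_names[k]`` measured at
    ``grids[0][i], grids[1][j]`` (1D tables drop the second axis).
    """

    param_names: tuple[str, ...]
    grids: tuple[np.ndarray, ...]
    cp_names: tuple[str, ...]
    values: np.ndarray

    def interp_forward(self, x: np.ndarray) -> np.ndarray:
        """Multilinear interpolation of the forward map at parameter
        point ``x`` (exact at grid nodes)."""
        from scipy.interpolate import RegularGridInterpolator
        out = np.empty(len(self.cp_names))
        for k in range(len(self.cp_names)):
            rgi = RegularGridInterpolator(self.grids, self.values[..., k],
                                          method="linear", bounds_error=True)
            out[k] = rgi(np.asarray(x)[None, :])[0]
        return out

    def hull(self) -> list[tuple[float, float]]:
        """Per-CP (min, max) over the grid."""
        return [(float(self.values[..., k].min()),
                 float(self.values[..., k].max()))
                for k in range(len(self.cp_names))]

    def check_monotone(self) -> None:
        """Each CP must be monotone along the axis that inverts it (axis k
        for CP k); offending cells are reported.  Violations smaller than
        0.5% of the CP range are tolerated (bisection quantization of the
        forward measurements)."""
        for k in range(len(self.cp_names)):
            v = self.values[..., k]
            d = np.diff(v, axis=k)
            eps = 5e-3 * np.ptp(v)
            if not (np.all(d > -eps) or np.all(d < eps)):
                sign = 1.0 if np.median(d) > 0 else -1.0
                bad = np.argwhere(sign * d <= -eps)
                raise ValueError(
                    f"forward map not monotone for CP {self.cp_names[k]!r} "
                    f"along {self.param_names[k]!r}; offending cells "
                    f"{bad[:5].tolist()}...")


def build_mn_active_lookup(base_rmp: MotoneuronRMP, cmp: MotoneuronCMP,
                           g_naf_grid: np.ndarray | None = None,
                           f_s_grid: np.ndarray | None = None,
                           n_grid: int = 21,
                           dt_ms: float = config.DT_MS) -> LookupTable:
    """Forward-measure (I_rheo, t_AHP_half) on a (G_Naf_S, f_S) grid.

    The base cell supplies the passive parameters under which the
    measurements are run; inversion for cells with different passive
    parameters refines against live measurement afterwards.
    """
    if g_naf_grid is None:
        g_naf_grid = np.linspace(30.0, 52.0, n_grid)
    if f_s_grid is None:
        f_s_grid = np.linspace(0.01, 0.06, n_grid)
    if g_naf_grid.size == 0 or f_s_grid.size == 0:
        raise ValueError("empty lookup grid")
    vals = np.empty((g_naf_grid.size, f_s_grid.size, 2))
    for i, g in enumerate(g_naf_grid):
        for j, fs in enumerate(f_s_grid):
            r = dataclasses.replace(base_rmp, g_naf_s=float(g), f_s=float(fs))
            i_rheo, t_ahp = mnm.measure_rheobase_ahp(r, cmp, upper_na=80.0,
                                                     dt_ms=dt_ms)
            vals[i, j] = (i_rheo, t_ahp)
    tab = LookupTable(("g_naf_s", "f_s"), (g_naf_grid, f_s_grid),
                      ("i_rheo", "t_ahp_half"), vals)
    tab.check_monotone()
    return tab


def build_pic_lookup(base_rmp: MotoneuronRMP, cmp: MotoneuronCMP,
                     g_cal_grid: np.ndarray | None = None,
                     n_grid: int = 13,
                     dt_ms: float = config.DT_MS) -> LookupTable:
    """Forward-measure PIC magnitude on a G_Cal_D grid (S_nm = 1,
    G_KCa_D = 0)."""
    if g_cal_grid is None:
        g_cal_grid = np.linspace(0.01, 0.16, n_grid)
    vals = np.empty((g_cal_grid.size, 1))
    for i, g in enumerate(g_cal_grid):
        r = dataclasses.replace(base_rmp, g_cal_d=float(g), g_kca_d=0.0,
                                s_nm=1.0)
        pic_mag, _, _ = mnm.measure_pic(r, cmp, dt_ms=dt_ms)
        vals[i, 0] = pic_mag
    tab = LookupTable(("g_cal_d",), (g_cal_grid,), ("pic_mag",), vals)
    tab.check_monotone()
    return tab


def invert_active(i_rheo: float, t_ahp_half: float, table: LookupTable,
                  base_rmp: MotoneuronRMP, cmp: MotoneuronCMP,
                  refine: bool = True, tol: float = 0.01,
                  max_iter: int = 6,
                  dt_ms: float = config.DT_MS) -> tuple[float, float]:
    """Invert (I_rheo, t_AHP_half) -> (G_Naf_S, f_S).

    Multilinear interpolation of the table gives the starting point; with
    ``refine`` the estimate is corrected against live forward measurement
    (quasi-Newton with the interpolated Jacobian) until both CPs match
    within ``tol`` relative error.  Targets outside the table's CP hull
    are refused.
    """
    hull = table.hull()
    for name, t, (lo, hi) in zip(table.cp_names, (i_rheo, t_ahp_half), hull):
        if not (lo <= t <= hi) and not refine:
            # without live refinement the table is authoritative: no
            # silent extrapolation
            raise ValueError(f"target {name}={t} outside lookup hull "
                             f"[{lo:.4g}, {hi:.4g}]")
    target = np.array([i_rheo, t_ahp_half])

    # invert the interpolated forward map
    g0 = np.array([table.grids[0].mean(), table.grids[1].mean()])

    def fun(x):
        x = np.clip(x, [table.grids[0][0], table.grids[1][0]],
                    [table.grids[0][-1], table.grids[1][-1]])
        return table.interp_forward(x) - target

    sol = root(fun, g0, method="hybr", options={"xtol": 1e-10})
    x = np.clip(sol.x, [table.grids[0][0], table.grids[1][0]],
                [table.grids[0][-1], table.grids[1][-1]])

    if not refine:
        return float(x[0]), float(x[1])

    # local bisection against live forward measurement, alternating the
    # two axes (t_AHP_half is governed by f_S, I_rheo by G_Naf_S; the
    # cross-couplings are weak, so one or two passes converge)
    g_lo, g_hi = float(table.grids[0][0]), float(table.grids[0][-1])
    f_lo, f_hi = float(table.grids[1][0]), float(table.grids[1][-1])
    g_naf, f_s = float(x[0]), float(x[1])

    def live_rheo(g, fs):
        r = dataclasses.replace(base_rmp, g_naf_s=g, f_s=fs)
        try:
            return mnm.measure_rheobase(r, cmp, upper_na=200.0, dt_ms=dt_ms)
        except RuntimeError:
            return np.inf  # no spiking: treat as arbitrarily high rheobase

    def live_ahp(g, fs):
        r = dataclasses.replace(base_rmp, g_naf_s=g, f_s=fs)
        return mnm.measure_ahp(r, cmp, dt_ms=dt_ms)

    def solve_1d(f, lo, hi, xtol):
        """Bracketed root of a monotone live measurement; clips to the
        nearer bound when the target is unreachable on the interval."""
        flo, fhi = f(lo), f(hi)
        if flo == 0.0:
            return lo
        if fhi == 0.0:
            return hi
        if np.sign(flo) == np.sign(fhi):
            return lo if abs(flo) < abs(fhi) else hi
        return brentq(f, lo, hi, xtol=xtol)

    for _ in range(max_iter):
        f_s = solve_1d(lambda fs: live_ahp(g_naf, fs) - t_ahp_half,
                       f_lo, f_hi, 1e-4)
        g_naf = solve_1d(lambda g: live_rheo(g, f_s) - i_rheo,
                         g_lo, g_hi, 0.05)
        meas = np.array([live_rheo(g_naf, f_s), live_ahp(g_naf, f_s)])
        if np.all(np.abs(meas - target) / np.abs(target) < tol):
            break
    return float(g_naf), float(f_s)


def invert_pic(pic_mag: float, table: LookupTable,
               base_rmp: MotoneuronRMP, cmp: MotoneuronCMP,
               pic_amp: float = 1.0, refine: bool = True,
               tol: float = 0.01, max_iter: int = 4,
               dt_ms: float = config.DT_MS) -> tuple[float, float]:
    """Invert PIC magnitude -> G_Cal_D (1D) and amplification -> S_nm.

    The clamp current depends only on the product S_nm * G_Cal_D, so
    pic_mag fixes the effective conductance g_eff = S_nm * G_Cal_D.  The
    amplification ratio M(g_eff)/M(g_eff/S_nm) -- with M the tabulated
    magnitude curve, sublinear because the unclamped dendrite depolarizes
    and loses driving force -- then determines S_nm by a 1-D root-find.
    """
    lo, hi = table.hull()[0]
    if not (lo <= pic_mag <= hi) and not refine:
        raise ValueError(f"target pic_mag={pic_mag} outside lookup hull "
                         f"[{lo:.4g}, {hi:.4g}]")
    mags, gs = table.values[:, 0], table.grids[0]
    g_eff = float(np.interp(pic_mag, mags, gs))
    if refine:
        slope = np.gradient(mags, gs)
        for _ in range(max_iter):
            r = dataclasses.replace(base_rmp, g_cal_d=g_eff, g_kca_d=0.0,
                                    s_nm=1.0)
            meas, _, _ = mnm.measure_pic(r, cmp, dt_ms=dt_ms)
            if abs(meas - pic_mag) / pic_mag < tol:
                break
            sl = float(np.interp(g_eff, gs, slope))
            g_eff = float(np.clip(g_eff + (pic_mag - meas) / sl,
                                  gs[0], gs[-1]))
    if pic_amp == 1.0:
        return g_eff, 1.0

    def M(g):
        return float(np.interp(np.clip(g, gs[0], gs[-1]), gs, mags))

    def resid(s):
        return M(g_eff) / M(g_eff / s) - pic_amp

    s_lo, s_hi = (1.0, 8.0) if pic_amp > 1.0 else (0.1, 1.0)
    if resid(s_lo) * resid(s_hi) > 0:
        s_nm = s_lo if abs(resid(s_lo)) < abs(resid(s_hi)) else s_hi
    else:
        s_nm = brentq(resid, s_lo, s_hi, xtol=1e-4)
    return g_eff / s_nm, float(s_nm)


# ---------------------------------------------------------------------------
# muscle-tendon inversion (staged, module order)


@dataclass
class MTCellProperties:
    """Inversion targets for one muscle-tendon fiber."""

    twitch_ct: float        # twitch contraction time (ms)
    twitch_hrt: float       # twitch half-relaxation time (ms)
    amp_ratio_long: float   # twitch amplitude at 0 mm / at -8 mm
    amp_ratio_short: float  # twitch amplitude at -16 mm / at -8 mm
    c1i: float              # calcium-force relation (module 2), direct
    c1n1: float
    c1n4: float
    c2i: float
    c2n1: float
    c2n4: float
    alpha_i: float
    beta: float             # movement-degradation coefficients, direct
    gamma: float
    p0_5: float             # peak isometric force at X_m,0.5 (N)
    fl_peak: float          # CE length of the force-length peak (mm)
    fl_hwhm: float          # force-length half-width at half maximum (mm)
    fv_vmax: float          # maximal shortening velocity (mm/s)
    fv_slope_short: float   # |d fv/dv| at v=0-, shortening branch (s/mm)
    fv_d0: float            # lengthening asymptote (dimensionless)
    fv_slope_len: float     # d fv/dv at v=0+, lengthening branch (s/mm)
    k_se: float             # series elastic stiffness (N/mm)
    a_muap: float = 0.3
    l_muap: float = 10.0


def _fv_coeffs(vmax: float, slope_short: float, d0: float,
               slope_len: float) -> tuple[float, float, float, float]:
    """Closed-form Hill/Mashima coefficients from the four velocity-force
    features; continuity fv(0)=1 holds by construction."""
    if slope_short * vmax <= 1.0:
        raise ValueError("infeasible FV: slope*vmax must exceed 1 on the "
                         "shortening branch")
    a_0 = 1.0 / (slope_short * vmax - 1.0)
    b_0 = a_0 * vmax
    if d0 <= 1.0 or slope_len <= 0:
        raise ValueError("infeasible FV: lengthening branch needs d0 > 1 "
                         "and positive slope")
    c_0 = (d0 - 1.0) / slope_len
    return a_0, b_0, c_0, d0


def invert_mt(cp: MTCellProperties, validate: bool = True,
              tol: float = 0.02, dt_ms: float = config.DT_MS,
              cmp: MuscleTendonCMP | None = None) -> MuscleTendonRMP:
    """Staged inversion of the fiber parameters in module order.

    Stage 1 (module 1): tau_1, tau_2 from the twitch contraction and
    half-relaxation times by 2-D root-finding on forward twitch
    simulations, seeded from the closed-form kernel peak time; then phi_1,
    phi_3 from the off-intermediate twitch amplitude ratios by bracketed
    1-D root-finds.  Stage 2 (module 2): the calcium-force and degradation
    coefficients are the fiber's own CPs (direct).  Stage 3 (module 3):
    g_1, g_2 in closed form from the force-length peak and half-width;
    Hill/Mashima coefficients in closed form from the velocity-force
    features; K_SE and P_0.5 direct (P_0.5 is enforced exactly by the
    construction-time calibration of the maximal CE force).
    """
    cmp = cmp or MuscleTendonCMP()
    g_1 = cp.fl_peak
    g_2 = cp.fl_hwhm / np.sqrt(np.log(2.0))
    a_0, b_0, c_0, d_0 = _fv_coeffs(cp.fv_vmax, cp.fv_slope_short,
                                    cp.fv_d0, cp.fv_slope_len)

    def make(tau_1, tau_2, phi_1=0.0, phi_3=0.0):
        return MuscleTendonRMP(
            tau_1=tau_1, tau_2=tau_2, phi_1=phi_1, phi_3=phi_3,
            c1i=cp.c1i, c1n1=cp.c1n1, c1n4=cp.c1n4,
            c2i=cp.c2i, c2n1=cp.c2n1, c2n4=cp.c2n4,
            alpha_i=cp.alpha_i, beta=cp.beta, gamma=cp.gamma,
            p0_5=cp.p0_5, g_1=g_1, g_2=g_2,
            a_0=a_0, b_0=b_0, c_0=c_0, d_0=d_0, k_se=cp.k_se,
            a_muap=cp.a_muap, l_muap=cp.l_muap)

    # --- stage 1a: twitch time constants.  The measured times are
    # quantized to the integration grid, so bracketing root-finders are
    # used (nested: tau_1 matches the contraction time at given tau_2,
    # the outer loop matches the half-relaxation time with tau_2).
    def metrics(t1, t2):
        _, ct, hrt = mtm.twitch_metrics(make(t1, t2), dt_ms=dt_ms, cmp=cmp)
        return ct, hrt

    def tau1_for_ct(t2):
        lo, hi = 0.5, 0.95 * t2

        def f(t1):
            return metrics(t1, t2)[0] - cp.twitch_ct

        flo, fhi = f(lo), f(hi)
        if flo > 0:
            return lo  # contraction time unreachable from below
        if fhi < 0:
            return hi
        return brentq(f, lo, hi, xtol=1e-3)

    def hrt_resid(t2):
        t1 = tau1_for_ct(t2)
        return metrics(t1, t2)[1] - cp.twitch_hrt, t1

    lo2, hi2 = 4.0, 400.0
    rlo, _ = hrt_resid(lo2)
    rhi, _ = hrt_resid(hi2)
    if rlo * rhi > 0:
        raise RuntimeError(
            "stage 1a (twitch dynamics) failed to bracket tau_2 for "
            f"half-relaxation time {cp.twitch_hrt}")
    tau_2 = brentq(lambda t2: hrt_resid(t2)[0], lo2, hi2, xtol=1e-3)
    tau_1 = tau1_for_ct(tau_2)

    # --- stage 1b: length-dependence rates
    def amp_at(rmp, x_mm):
        peak, _, _ = mtm.twitch_metrics(rmp, x_m_mm=x_mm, dt_ms=dt_ms,
                                        cmp=cmp)
        return peak

    base = make(tau_1, tau_2)
    a_mid = amp_at(base, cmp.x_half)

    def f3(phi):
        r = make(tau_1, tau_2, 0.0, phi)
        return amp_at(r, 0.0) / amp_at(r, cmp.x_half) - cp.amp_ratio_long

    def f1(phi):
        r = make(tau_1, tau_2, phi, 0.0)
        return amp_at(r, -16.0) / amp_at(r, cmp.x_half) - cp.amp_ratio_short

    try:
        phi_3 = brentq(f3, 0.0, 0.5, xtol=1e-5) if f3(0.0) < 0 else 0.0
    except ValueError as e:
        raise RuntimeError(f"stage 1b (phi_3) failed to bracket: {e}")
    try:
        phi_1 = brentq(f1, 0.0, 0.5, xtol=1e-5) if f1(0.0) > 0 else 0.0
    except ValueError as e:
        raise RuntimeError(f"stage 1b (phi_1) failed to bracket: {e}")

    rmp = make(tau_1, tau_2, phi_1, phi_3)

    if validate:
        _, ct, hrt = mtm.twitch_metrics(rmp, dt_ms=dt_ms, cmp=cmp)
        for got, want, name in ((ct, cp.twitch_ct, "contraction time"),
                                (hrt, cp.twitch_hrt, "half-relaxation time")):
            if abs(got - want) / want > tol:
                raise RuntimeError(
                    f"muscle inversion validation failed: {name} {got:.2f} "
                    f"vs target {want:.2f}")
    return rmp


def measure_mt_cp(rmp: MuscleTendonRMP, cmp: MuscleTendonCMP | None = None,
                  dt_ms: float = config.DT_MS) -> MTCellProperties:
    """Forward-measure the inversion targets of a fiber (used to derive
    correlation tables from presets and in round-trip tests)."""
    cmp = cmp or MuscleTendonCMP()
    _, ct, hrt = mtm.twitch_metrics(rmp, dt_ms=dt_ms, cmp=cmp)
    a_mid, _, _ = mtm.twitch_metrics(rmp, x_m_mm=cmp.x_half, dt_ms=dt_ms,
                                     cmp=cmp)
    a_long, _, _ = mtm.twitch_metrics(rmp, x_m_mm=0.0, dt_ms=dt_ms, cmp=cmp)
    a_short, _, _ = mtm.twitch_metrics(rmp, x_m_mm=-16.0, dt_ms=dt_ms,
                                       cmp=cmp)
    slope_short = (1.0 + rmp.a_0) / rmp.b_0
    slope_len = (rmp.d_0 - 1.0) / rmp.c_0
    return MTCellProperties(
        twitch_ct=ct, twitch_hrt=hrt,
        amp_ratio_long=a_long / a_mid, amp_ratio_short=a_short / a_mid,
        c1i=rmp.c1i, c1n1=rmp.c1n1, c1n4=rmp.c1n4,
        c2i=rmp.c2i, c2n1=rmp.c2n1, c2n4=rmp.c2n4,
        alpha_i=rmp.alpha_i, beta=rmp.beta, gamma=rmp.gamma,
        p0_5=rmp.p0_5, fl_peak=rmp.g_1,
        fl_hwhm=rmp.g_2 * np.sqrt(np.log(2.0)),
        fv_vmax=rmp.b_0 / rmp.a_0, fv_slope_short=slope_short,
        fv_d0=rmp.d_0, fv_slope_len=slope_len, k_se=rmp.k_se,
        a_muap=rmp.a_muap, l_muap=rmp.l_muap)


# ---------------------------------------------------------------------------
# correlation curves CP = g(CI)


@dataclass
class CorrelationCurve:
    """One named CI -> CP curve.

    kinds: ``linear`` (c0 + c1*ci), ``exponential_decay``
    (c0*exp(-c1*ci) + c2), ``piecewise`` (linear segments between
    breakpoints with a jump allowed at each interior breakpoint:
    coefficients are x0,y0,x1,y1,... evaluated on the segment whose left
    node is the largest x <= ci), ``tabulated`` (linear interpolation of
    (ci, value) pairs), ``constant`` (c0).
    """

    cp_name: str
    kind: str
    coeffs: np.ndarray
    domain: tuple[float, float] = (-np.inf, np.inf)

    def __call__(self, ci: float) -> float:
        lo, hi = self.domain
        if not (lo <= ci <= hi):
            raise ValueError(f"CI {ci} outside domain [{lo}, {hi}] of "
                             f"curve {self.cp_name!r}")
        c = self.coeffs
        if self.kind == "constant":
            return float(c[0])
        if self.kind == "linear":
            return float(c[0] + c[1] * ci)
        if self.kind == "exponential_decay":
            return float(c[0] * np.exp(-c[1] * ci) + c[2])
        if self.kind == "piecewise":
            xs, ys = c[0::2], c[1::2]
            idx = int(np.searchsorted(xs, ci, side="right")) - 1
            idx = max(0, min(idx, xs.size - 2))
            x0, x1 = xs[idx], xs[idx + 1]
            y0, y1 = ys[idx], ys[idx + 1]
            if x1 == x0:
                return float(y0)
            return float(y0 + (y1 - y0) * (ci - x0) / (x1 - x0))
        if self.kind == "tabulated":
            xs, ys = c[0::2], c[1::2]
            if not np.all(np.diff(xs) > 0):
                raise ValueError("tabulated curve must be strictly ordered")
            return float(np.interp(ci, xs, ys))
        raise ValueError(f"unknown curve kind {self.kind!r}")


@dataclass
class CorrelationSet:
    """Named CI -> CP curves keyed by CP name, with the CI name recorded."""

    ci_name: str
    curves: dict[str, CorrelationCurve]

    def __call__(self, ci: float) -> dict[str, float]:
        return {name: curve(ci) for name, curve in self.curves.items()}

    def to_csv(self, path) -> None:
        rows = []
        for name, c in self.curves.items():
            rows.append({"ci_name": self.ci_name, "cp_name": name,
                         "curve_type": c.kind,
                         "domain_lo": c.domain[0], "domain_hi": c.domain[1],
                         "coeffs": ";".join(f"{v:.10g}" for v in c.coeffs)})
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CorrelationSet":
        df = pd.read_csv(path)
        curves = {}
        ci_names = df.ci_name.unique()
        if len(ci_names) != 1:
            raise ValueError("correlation CSV must use a single CI")
        for _, row in df.iterrows():
            coeffs = np.array([float(v) for v in str(row.coeffs).split(";")])
            curves[row.cp_name] = CorrelationCurve(
                row.cp_name, row.curve_type, coeffs,
                (float(row.domain_lo), float(row.domain_hi)))
        return cls(str(ci_names[0]), curves)

    def override(self, cp_name: str, curve: CorrelationCurve) -> None:
        """User-imported replacement of one correlation (e.g. updating the
        linear twitch-speed relation to an exponential decay)."""
        self.curves[cp_name] = curve


def load_default_correlations(kind: str) -> CorrelationSet:
    """Shipped placeholder correlation sets (synthetic, fitted through the
    shipped presets; see data/ and docs/methods.md)."""
    import importlib.resources
    fname = {"MN": "correlations_mn_rn.csv",
             "MT": "correlations_mt_p05.csv",
             "MU": "correlations_mu_rn.csv"}[kind]
    with importlib.resources.as_file(
            importlib.resources.files("neuromuscle.data") / fname) as p:
        return CorrelationSet.from_csv(p)


def cp_from_ci(ci: float, correlations: CorrelationSet) -> dict[str, float]:
    """Evaluate every correlation curve at one cell-indicator value."""
    return correlations(ci)


# ---------------------------------------------------------------------------
# population construction


def ci_rank_distribution(n: int, ci_min: float, ci_max: float,
                         gamma: float = 1.0) -> np.ndarray:
    """Cell-indicator values over rank: ci_i = ci_min + span * (i/(n-1))^gamma.

    gamma < 1 concentrates cells near ci_max (for R_N: an S-dominant
    pool); gamma = 1 is linear; gamma > 1 concentrates near ci_min
    (F-dominant).
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    if n == 1:
        return np.array([0.5 * (ci_min + ci_max)])
    u = (np.arange(n) / (n - 1.0)) ** gamma
    return ci_min + (ci_max - ci_min) * u


@dataclass
class PopulationSpec:
    """Recipe for a heterogeneous pool."""

    cell_kind: str                  # MN, MT, or MU
    ci_values: np.ndarray           # one CI per cell (R_N or P_0.5)
    correlations: CorrelationSet | None = None  # default set if None
    cmp_preset: str = "FR"          # preset supplying the constants
    mt_cmp_preset: str = "SOL"      # fiber constants for MU pools
    refine: bool = True             # live refinement of active inversions
    lookup_n_grid: int = 21         # nodes per axis of the active lookup

    def __post_init__(self) -> None:
        self.ci_values = np.asarray(self.ci_values, dtype=float)
        if self.cell_kind not in ("MN", "MT", "MU"):
            raise ValueError(f"unknown cell kind {self.cell_kind!r}")
        if self.ci_values.size < 1 or np.any(self.ci_values <= 0):
            raise ValueError("ci_values must be positive and non-empty")


@dataclass
class Pool:
    """Fully parameterized population with per-cell provenance."""

    cell_kind: str
    cells: list                    # MotorUnitParams | (rmp, cmp) tuples
    provenance: pd.DataFrame       # one row per cell: ci, CPs, RMPs

    def __len__(self) -> int:
        return len(self.cells)


def _invert_mn_cell(cps: dict[str, float], cmp: MotoneuronCMP,
                    active_tab: LookupTable, pic_tab: LookupTable,
                    base_rmp: MotoneuronRMP,
                    refine: bool) -> MotoneuronRMP:
    passive = invert_passive(cps["r_n"], cps["tau_m"], cps["va_sd_dc"],
                             cps["va_ds_dc"], cps["va_sd_ac"], cmp)
    cell = dataclasses.replace(base_rmp, **passive,
                               d_path=cps.get("d_path", base_rmp.d_path))
    g_naf, f_s = invert_active(cps["i_rheo"], cps["t_ahp_half"], active_tab,
                               cell, cmp, refine=refine)
    cell = dataclasses.replace(cell, g_naf_s=g_naf, f_s=f_s)
    if "pic_mag" in cps:
        g_cal, s_nm = invert_pic(cps["pic_mag"], pic_tab, cell, cmp,
                                 pic_amp=cps.get("pic_amp", 1.0),
                                 refine=refine)
    else:
        # stated defaults when no PIC properties are supplied
        g_cal, s_nm = 0.0, 1.0
    return dataclasses.replace(cell, g_cal_d=g_cal, g_kca_d=0.0, s_nm=s_nm)


def _mt_cp_from_corr(cps: dict[str, float]) -> MTCellProperties:
    names = [f.name for f in dataclasses.fields(MTCellProperties)]
    missing = [n for n in names if n not in cps
               and n not in ("a_muap", "l_muap")]
    if missing:
        raise ValueError(f"correlation set missing MT properties: {missing}")
    return MTCellProperties(**{n: cps[n] for n in names if n in cps})


_LOOKUP_CACHE: dict = {}


def build_population(spec: PopulationSpec) -> Pool:
    """Construct a pool: per cell, CP_i = g(CI_i) then RMP_i = f^-1(CP_i).

    Deterministic: no randomness enters anywhere.  Any per-cell inversion
    failure aborts with the cell index and stage.
    """
    corr = spec.correlations or load_default_correlations(spec.cell_kind)
    cells: list = []
    prov_rows = []

    if spec.cell_kind in ("MN", "MU"):
        base_rmp, mn_cmp = nio.load_preset("MN", spec.cmp_preset)
        # lookup tables are built once under the reference preset's passive
        # cell (verified monotone there); per-cell live refinement absorbs
        # the passive-parameter differences across the pool.  Tables are
        # memoized per preset: they are pure functions of the preset.
        key = (spec.cmp_preset, spec.lookup_n_grid)
        if key not in _LOOKUP_CACHE:
            _LOOKUP_CACHE[key] = (
                build_mn_active_lookup(base_rmp, mn_cmp,
                                       n_grid=spec.lookup_n_grid),
                build_pic_lookup(base_rmp, mn_cmp))
        active_tab, pic_tab = _LOOKUP_CACHE[key]
    if spec.cell_kind == "MU":
        _, mt_cmp = nio.load_preset("MT", spec.mt_cmp_preset)
    elif spec.cell_kind == "MT":
        _, mt_cmp = nio.load_preset("MT", spec.cmp_preset
                                    if spec.cmp_preset in nio.MT_PRESETS
                                    else spec.mt_cmp_preset)

    for idx, ci in enumerate(spec.ci_values):
        try:
            cps = corr(float(ci))
            if spec.cell_kind in ("MN", "MU"):
                cps.setdefault("r_n", float(ci))
            else:
                cps.setdefault("p0_5", float(ci))
            if spec.cell_kind == "MN":
                rmp = _invert_mn_cell(cps, mn_cmp, active_tab, pic_tab,
                                      base_rmp, spec.refine)
                cells.append((rmp, mn_cmp))
                prov_rows.append({"cell": idx, "ci": ci, **cps,
                                  **dataclasses.asdict(rmp)})
            elif spec.cell_kind == "MT":
                mt_rmp = invert_mt(_mt_cp_from_corr(cps), cmp=mt_cmp)
                cells.append((mt_rmp, mt_cmp))
                prov_rows.append({"cell": idx, "ci": ci, **cps,
                                  **dataclasses.asdict(mt_rmp)})
            else:  # MU: MN keyed by R_N; fiber through the R_N -> P_0.5 link
                rmp = _invert_mn_cell(cps, mn_cmp, active_tab, pic_tab,
                                      base_rmp, spec.refine)
                mt_rmp = invert_mt(_mt_cp_from_corr(cps), cmp=mt_cmp)
                cv = cps.get("cv", 60.0)
                cells.append(MotorUnitParams(rmp, mn_cmp, mt_rmp, mt_cmp,
                                             cv=cv))
                prov_rows.append({"cell": idx, "ci": ci, **cps,
                                  **{f"mn_{k}": v for k, v in
                                     dataclasses.asdict(rmp).items()},
                                  **{f"mt_{k}": v for k, v in
                                     dataclasses.asdict(mt_rmp).items()}})
        except Exception as e:
            raise RuntimeError(
                f"population construction failed at cell {idx} "
                f"(CI={ci:.4g}): {e}") from e
    return Pool(spec.cell_kind, cells, pd.DataFrame(prov_rows))
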