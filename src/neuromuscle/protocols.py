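"""Builders for the standard stimulation scenarios.

These compose the signal generators into the protocol battery used by the
analyses and tests: slow triangular ramps at the 450%-Ia-equivalent level
(somatic current or dendritic conductance), the bistability step protocol,
motor-unit pool drives under the three inhibition schemes, and the
fixed-somatic-drive protocol at four muscle lengths.
"""

from __future__ import annotations

import numpy as np

from . import config
from .engine import CellDrive, DriveSet
from .signals import (Signal, SynapticDrive, gen_constant, gen_length_profile,
                      gen_step_with_pulses, gen_synaptic_drive,
                      gen_triangular)

#: Bistability step protocol constants (nA, ms).  The step sits inside the
#: FR cell's bistable window; the brief excitatory pulse latches the
#: dendritic PIC plateau and the strong brief inhibitory pulse deactivates
#: it (it must overcome the soma-dendrite coupling anchor).
BISTAB_STEP_NA = 10.0
BISTAB_EXC_PULSE_NA = 20.0
BISTAB_INH_PULSE_NA = 60.0
BISTAB_PULSE_MS = 50.0
BISTAB_DELAY_MS = 10000.0

#: Pool scenario constants.  The ramp peak is sized so that every unit of
#: the shipped pools is recruited comfortably within the ascending phase
#: while recruitment stays staggered across it (about twice the highest
#: recruitment threshold of the default cell-indicator range); background
#: inhibition and its noise are moderate fractions of that drive.
POOL_GE_PEAK = 0.2
POOL_GI_BASE = 0.05
POOL_NOISE_SD = 0.01
POOL_NOISE_TAU_MS = 20.0


def triangular_current(peak_na: float = config.IA450_CURRENT_NA,
                       T_ms: float = 22000.0,
                       dt_ms: float = config.DT_MS) -> Signal:
    """Slow symmetric triangular somatic-current ramp."""
    return gen_triangular(peak_na, T_ms / 2.0, T_ms, dt_ms)


def triangular_conductance_drive(peak: float = config.IA450_CONDUCTANCE,
                                 T_ms: float = 22000.0,
                                 dt_ms: float = config.DT_MS) -> SynapticDrive:
    """Noise-free triangular excitatory dendritic conductance."""
    ge = gen_triangular(peak, T_ms / 2.0, T_ms, dt_ms)
    return gen_synaptic_drive(ge, "constant_inhibition", 0.0)


def bistability_current(step_na: float = BISTAB_STEP_NA,
                        exc_pulse_na: float = BISTAB_EXC_PULSE_NA,
                        inh_pulse_na: float = BISTAB_INH_PULSE_NA,
                        pulse_ms: float = BISTAB_PULSE_MS,
                        delay_ms: float = BISTAB_DELAY_MS,
                        T_ms: float = 13000.0,
                        dt_ms: float = config.DT_MS) -> Signal:
    """Long step with a brief excitatory pulse at onset and a delayed
    brief inhibitory pulse (amplitudes may differ)."""
    base = gen_step_with_pulses(0.0, step_na, exc_pulse_na, pulse_ms,
                                delay_ms, T_ms, dt_ms)
    v = base.values.copy()
    t = base.times
    mask = (t >= delay_ms) & (t < delay_ms + pulse_ms)
    v[mask] = step_na - inh_pulse_na
    return Signal(0.0, dt_ms, v)


def pool_synaptic_drives(n_cells: int, scheme: str,
                         ge_peak: float = POOL_GE_PEAK,
                         gi_base: float = POOL_GI_BASE,
                         noise_sd: float = POOL_NOISE_SD,
                         x_m_mm: float = config.XM_INTERMEDIATE_MM,
                         T_ms: float = 20000.0,
                         dt_ms: float = config.DT_MS,
                         seed: int = 0) -> DriveSet:
    """Per-cell triangular excitatory drives under one inhibition scheme
    with independent noise realizations, at a fixed (isometric) length."""
    ge = gen_triangular(ge_peak, T_ms / 2.0, T_ms, dt_ms)
    xm = gen_constant(x_m_mm, T_ms, dt_ms)
    drives = []
    for i in range(n_cells):
        cell_seed = seed * 100003 + i
        drives.append(CellDrive(
            drive=gen_synaptic_drive(ge, scheme, gi_base, noise_sd,
                                     POOL_NOISE_TAU_MS, cell_seed),
            x_m=xm, seed=cell_seed))
    return DriveSet(drives, dt_ms, T_ms)


def pool_current_drives(n_cells: int, peak_na: float = 40.0,
                        t_peak_ms: float = 5000.0, T_ms: float = 10000.0,
                        x_m_mm: float = config.XM_INTERMEDIATE_MM,
                        dt_ms: float = config.DT_MS) -> DriveSet:
    """Identical triangular somatic-current drive to every cell (the
    fixed-drive, length-variation scenario; no noise)."""
    cur = gen_triangular(peak_na, t_peak_ms, T_ms, dt_ms)
    xm = gen_constant(x_m_mm, T_ms, dt_ms)
    drives = [CellDrive(i_soma=cur, x_m=xm) for _ in range(n_cells)]
    return DriveSet(drives, dt_ms, T_ms)


def length_battery(dt_ms: float = config.DT_MS) -> dict[str, Signal]:
    """The five muscle-length protocols (isometric at the intermediate
    length, isokinetic shortening/lengthening, step shortening, and the
    ~5 Hz locomotor-like sinusoid)."""
    T = 3000.0
    return {
        "isometric": gen_length_profile("isometric", {"length": -8.0}, T,
                                        dt_ms),
        "isokinetic_shortening": gen_length_profile(
            "isokinetic_ramp", {"start": 0.0, "end": -12.0,
                                "t_start": 500.0, "t_end": 2500.0}, T, dt_ms),
        "isokinetic_lengthening": gen_length_profile(
            "isokinetic_ramp", {"start": -16.0, "end": -4.0,
                                "t_start": 500.0, "t_end": 2500.0}, T, dt_ms),
        "step_shortening": gen_length_profile(
            "step_shortening", {"start": -8.0, "step": -3.0,
                                "t_step": 1500.0}, T, dt_ms),
        "locomotor": gen_length_profile(
            "locomotor_sinusoid", {"offset": -8.0, "amplitude": 4.0,
                                   "freq_hz": 5.0}, T, dt_ms),
    }
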