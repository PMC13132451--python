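"""Motor unit: one motoneuron coupled to one lumped muscle-tendon fiber.

The axon transmits every somatic action potential one-to-one to the
muscle unit with a pure conduction delay ``axon_length / CV``; spikes
whose delayed arrival falls beyond the simulation window are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import config
from .motoneuron import (MNTrace, MotoneuronCMP, MotoneuronRMP, simulate_mn)
from .muscle_tendon import (MTTrace, MuscleTendonCMP, MuscleTendonRMP,
                            simulate_mt)
from .signals import Signal, SpikeTrain, SynapticDrive


@dataclass
class MotorUnitParams:
    mn_rmp: MotoneuronRMP
    mn_cmp: MotoneuronCMP
    mt_rmp: MuscleTendonRMP
    mt_cmp: MuscleTendonCMP = field(default_factory=MuscleTendonCMP)
    cv: float = 60.0                      # axonal conduction velocity (m/s)
    axon_length: float = config.AXON_LENGTH_MM  # conduction distance (mm)

    def __post_init__(self) -> None:
        if self.cv <= 0:
            raise ValueError("conduction velocity must be positive")
        if self.axon_length < 0:
            raise ValueError("axon length must be non-negative")

    @property
    def delay_ms(self) -> float:
        # mm / (m/s) = ms
        return self.axon_length / self.cv


def delayed_train(spike_times: np.ndarray, delay_ms: float,
                  T_ms: float) -> SpikeTrain:
    """Delay somatic spikes by the conduction time; arrivals beyond the
    simulation window are dropped."""
    t = np.asarray(spike_times, dtype=float) + delay_ms
    return SpikeTrain(t[t < T_ms])


def simulate_mu(params: MotorUnitParams,
                i_soma: Signal | None = None,
                drive: SynapticDrive | None = None,
                x_m: Signal | None = None,
                dt_ms: float = config.DT_MS,
                T_ms: float | None = None,
                initial: np.ndarray | None = None) -> tuple[MNTrace, MTTrace]:
    """Simulate the motoneuron, deliver its spikes through the axon, and
    simulate the muscle-tendon fiber on the delayed train."""
    if T_ms is None:
        for s in (i_soma, drive.g_e if drive else None, x_m):
            if s is not None:
                T_ms = s.duration
                break
        if T_ms is None:
            raise ValueError("T_ms required when no input signal is given")
    mn_tr = simulate_mn(params.mn_rmp, params.mn_cmp, i_soma=i_soma,
                        drive=drive, dt_ms=dt_ms, T_ms=T_ms, initial=initial)
    train = delayed_train(mn_tr.spike_times, params.delay_ms, T_ms)
    mt_tr = simulate_mt(params.mt_rmp, train, x_m=x_m, dt_ms=dt_ms,
                        T_ms=T_ms, cmp=params.mt_cmp)
    return mn_tr, mt_tr
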