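"""Pool execution engine and aggregate analyses.

Cells are pure functions of (parameters, drive, seed): they share no
state, so a pool run is embarrassingly parallel.  The execution contract
is that serial and local-parallel backends produce bit-identical results
for any worker count, because each cell's computation is identical and
aggregation always sums in cell-index order.

Aggregates: total force and intramuscular EMG (iEMG) are exact
elementwise sums of the per-cell force and MUAP signals; the iEMG
envelope is a centered moving RMS; mean pool firing rate is the average
of Hann-smoothed per-cell instantaneous rates over active cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config
from .motor_unit import MotorUnitParams, simulate_mu
from .motoneuron import MNTrace, simulate_mn
from .muscle_tendon import MTTrace, simulate_mt
from .signals import Signal, SpikeTrain, SynapticDrive


@dataclass
class CellDrive:
    """Inputs for one cell (the subset applicable to its kind)."""

    i_soma: Signal | None = None
    drive: SynapticDrive | None = None
    spikes: SpikeTrain | None = None
    x_m: Signal | None = None
    seed: int = 0


@dataclass
class DriveSet:
    """Per-cell input assignment on a shared grid."""

    drives: list[CellDrive]
    dt: float
    T: float

    def __len__(self) -> int:
        return len(self.drives)


@dataclass
class PoolResult:
    """Per-cell traces and exact-sum aggregates."""

    cell_kind: str
    mn_traces: list[MNTrace | None]
    mt_traces: list[MTTrace | None]
    total_force: np.ndarray
    iemg: np.ndarray
    dt: float
    backend: str
    n_workers: int

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.total_force.size)

    def rms_envelope(self, window_ms: float = config.RMS_WINDOW_MS) -> np.ndarray:
        return rms_envelope(Signal(0.0, self.dt, self.iemg), window_ms).values

    def mean_rate(self, window_ms: float = config.HANN_WINDOW_MS) -> np.ndarray:
        """Mean smoothed firing rate over active cells (>= 2 spikes)."""
        n = self.total_force.size
        rates = []
        for tr in self.mn_traces:
            if tr is None or tr.spike_times.size < 2:
                continue
            grid = rate_on_grid(tr, self.dt, n)
            rates.append(smooth_rate(grid, _hann_len(window_ms, self.dt)))
        if not rates:
            return np.zeros(n)
        return np.mean(rates, axis=0)


def _run_cell(cell, cd: CellDrive, dt: float, T: float):
    if isinstance(cell, MotorUnitParams):
        mn_tr, mt_tr = simulate_mu(cell, i_soma=cd.i_soma, drive=cd.drive,
                                   x_m=cd.x_m, dt_ms=dt, T_ms=T)
        return mn_tr, mt_tr
    rmp, cmp = cell
    if type(rmp).__name__ == "MotoneuronRMP":
        return simulate_mn(rmp, cmp, i_soma=cd.i_soma, drive=cd.drive,
                           dt_ms=dt, T_ms=T), None
    return None, simulate_mt(rmp, cd.spikes or SpikeTrain(np.empty(0)),
                             x_m=cd.x_m, dt_ms=dt, T_ms=T, cmp=cmp)


def run_pool(pool, drives: DriveSet, backend: str = "serial",
             n_workers: int = 1) -> PoolResult:
    """Simulate every cell independently and aggregate in index order.

    ``backend``: ``serial`` runs in-process; ``local_parallel`` fans cells
    out to worker processes (joblib/loky).  Results are bit-identical
    across backends and worker counts.  Any cell failures are collected
    and reported together with their indices.
    """
    cells = pool.cells if hasattr(pool, "cells") else list(pool)
    kind = getattr(pool, "cell_kind", "MU")
    if len(cells) != len(drives):
        raise ValueError(f"pool has {len(cells)} cells but drive set has "
                         f"{len(drives)}")
    dt, T = drives.dt, drives.T

    if backend == "serial":
        outs, errors = [], []
        for i, (cell, cd) in enumerate(zip(cells, drives.drives)):
            try:
                outs.append(_run_cell(cell, cd, dt, T))
            except Exception as e:
                outs.append(None)
                errors.append((i, str(e)))
    elif backend == "local_parallel":
        from joblib import Parallel, delayed
        raw = Parallel(n_jobs=max(1, n_workers))(
            delayed(_safe_run)(cell, cd, dt, T)
            for cell, cd in zip(cells, drives.drives))
        outs = [r if not isinstance(r, str) else None for r in raw]
        errors = [(i, r) for i, r in enumerate(raw) if isinstance(r, str)]
    else:
        raise ValueError(f"unknown backend {backend!r}")

    if errors:
        idx = [i for i, _ in errors]
        raise RuntimeError(f"cell failures at indices {idx}: "
                           f"{errors[:3]} (partial results retained)")

    n = int(round(T / dt)) + 1
    total_force = np.zeros(n)
    iemg = np.zeros(n)
    mn_traces, mt_traces = [], []
    for mn_tr, mt_tr in outs:  # summation order fixed to cell index
        mn_traces.append(mn_tr)
        mt_traces.append(mt_tr)
        if mt_tr is not None:
            total_force += mt_tr.force
            iemg += mt_tr.muap
    return PoolResult(kind, mn_traces, mt_traces, total_force, iemg, dt,
                      backend, n_workers)


def _safe_run(cell, cd, dt, T):
    try:
        return _run_cell(cell, cd, dt, T)
    except Exception as e:  # serialized back as a string marker
        return f"{type(e).__name__}: {e}"


# ---------------------------------------------------------------------------
# aggregate signal analyses


def rms_envelope(signal: Signal, window_ms: float) -> Signal:
    """Centered moving RMS of a signal."""
    if window_ms <= 0:
        raise ValueError("window must be positive")
    w = int(round(window_ms / signal.dt))
    if w < 1:
        raise ValueError("window shorter than the sample interval")
    if w % 2 == 0:
        w += 1
    sq = signal.values ** 2
    kernel = np.ones(w)
    num = np.convolve(sq, kernel, mode="same")
    den = np.convolve(np.ones_like(sq), kernel, mode="same")
    return Signal(signal.t0, signal.dt, np.sqrt(num / den))


def _hann_len(window_ms: float, dt: float) -> int:
    n = int(round(window_ms / dt))
    if n % 2 == 0:
        n += 1
    return max(n, 3)


def smooth_rate(series: np.ndarray, window: int) -> np.ndarray:
    """Convolution with a normalized Hann window; edges use renormalized
    partial windows so a constant series is unchanged."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    h = np.hanning(window)
    num = np.convolve(series, h, mode="same")
    den = np.convolve(np.ones_like(series), h, mode="same")
    return num / den


def rate_on_grid(tr: MNTrace, dt: float, n: int) -> np.ndarray:
    """Instantaneous firing rate resampled to the shared grid: between
    spikes k-1 and k the rate is 1000/ISI_k; zero before the second spike
    and after the last."""
    out = np.zeros(n)
    st = tr.spike_times
    for k in range(1, st.size):
        i0 = int(np.floor(st[k - 1] / dt))
        i1 = min(int(np.floor(st[k] / dt)) + 1, n)
        out[i0:i1] = 1000.0 / (st[k] - st[k - 1])
    return out


def emg_force_curve(envelope: np.ndarray, total_force: np.ndarray,
                    dt: float,
                    onset_delay_ms: float = config.EMG_FORCE_ONSET_DELAY_MS
                    ) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalized iEMG-force relation and its curvature index.

    Discards the first ``onset_delay_ms`` (force development lag),
    normalizes both channels to their maxima, and returns (iemg_n,
    force_n, curvature).  The curvature index is the signed area between
    the force-vs-iEMG curve and the identity diagonal: 0 for a linear
    relation, negative when force lags iEMG (superlinear force), positive
    when force leads (sublinear).
    """
    if onset_delay_ms < 0:
        raise ValueError("onset delay must be non-negative")
    k = int(round(onset_delay_ms / dt))
    e = np.asarray(envelope, dtype=float)[k:]
    f = np.asarray(total_force, dtype=float)[k:]
    if e.size == 0 or e.max() <= 0 or f.max() <= 0:
        raise ValueError("degenerate input: zero maxima after onset cut")
    e = e / e.max()
    f = f / f.max()
    order = np.argsort(e)
    e_s, f_s = e[order], f[order]
    curvature = float(np.trapezoid(f_s - e_s, e_s))
    return e, f, curvature
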