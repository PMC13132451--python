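"""Stimulation-protocol signals: currents, conductances, spike trains, lengths.

Every generator returns a uniformly sampled :class:`Signal` with
``round(T/dt) + 1`` samples (sample-and-hold between grid points), or a
:class:`SpikeTrain` of event times.  Synaptic drives combine an excitatory
conductance with an inhibitory one under one of three inhibition schemes and
optional exponentially correlated (Ornstein-Uhlenbeck) conductance noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import config


def _n_samples(T_ms: float, dt_ms: float) -> int:
    return int(round(T_ms / dt_ms)) + 1


@dataclass
class Signal:
    """Uniformly sampled time series.

    Units depend on the channel: nA for currents, mS/cm2 for conductances,
    mm for muscle-tendon lengths.
    """

    t0: float
    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * (self.values.size - 1)

    def at(self, t: float) -> float:
        """Sample-and-hold evaluation at time ``t`` (ms)."""
        idx = int(np.floor((t - self.t0) / self.dt + 1e-9))
        idx = min(max(idx, 0), self.values.size - 1)
        return float(self.values[idx])

    def resampled_to(self, dt: float, T: float) -> "Signal":
        """Sample-and-hold resampling onto a [0, T] grid with step ``dt``."""
        n = _n_samples(T, dt)
        t = dt * np.arange(n)
        idx = np.clip(np.floor((t - self.t0) / self.dt + 1e-9).astype(int),
                      0, self.values.size - 1)
        return Signal(0.0, dt, self.values[idx])

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.values]),
                   delimiter=",", header="time_ms,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "Signal":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        t, v = arr[:, 0], arr[:, 1]
        if t.size < 2:
            raise ValueError("signal CSV needs at least two samples")
        dts = np.diff(t)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValueError("signal CSV must be uniformly sampled")
        return cls(float(t[0]), float(dts[0]), v)


@dataclass
class SpikeTrain:
    """Ordered axonal stimulation events (ms)."""

    spike_times: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0:
                raise ValueError("spike times must be non-negative")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def shifted(self, delay_ms: float) -> "SpikeTrain":
        return SpikeTrain(self.spike_times + delay_ms)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.spike_times,
                                          np.ones_like(self.spike_times)]),
                   delimiter=",", header="time_ms,value", comments="")

    @classmethod
    def from_csv(cls, path) -> "SpikeTrain":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(arr[:, 0] if arr.size else np.empty(0))


SCHEMES = ("constant_inhibition", "balanced", "push_pull")


@dataclass
class SynapticDrive:
    """Paired excitatory/inhibitory dendritic conductance waveforms."""

    g_e: Signal
    g_i: Signal
    scheme: str = "constant_inhibition"
    noise_sd: float = 0.0
    noise_tau: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if np.any(self.g_e.values < 0) or np.any(self.g_i.values < 0):
            raise ValueError("synaptic conductances must be non-negative")


# ---------------------------------------------------------------------------
# generators


def gen_constant(value: float, T_ms: float, dt_ms: float) -> Signal:
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    return Signal(0.0, dt_ms, np.full(_n_samples(T_ms, dt_ms), float(value)))


def gen_step_with_pulses(baseline: float, step_amp: float, pulse_amp: float,
                         pulse_width_ms: float, pulse_delay_ms: float,
                         T_ms: float, dt_ms: float) -> Signal:
    """Long step with a brief excitatory pulse at onset and a delayed
    inhibitory pulse of the same width (the bistability protocol)."""
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if not (0 <= pulse_delay_ms and pulse_delay_ms + pulse_width_ms <= T_ms):
        raise ValueError("pulse lies outside [0, T]")
    t = dt_ms * np.arange(_n_samples(T_ms, dt_ms))
    v = np.full(t.size, baseline + step_amp)
    v[t < pulse_width_ms] += pulse_amp
    v[(t >= pulse_delay_ms) & (t < pulse_delay_ms + pulse_width_ms)] -= pulse_amp
    return Signal(0.0, dt_ms, v)


def gen_triangular(peak: float, t_peak_ms: float, T_ms: float,
                   dt_ms: float) -> Signal:
    """Linear rise 0 -> peak over [0, t_peak], fall peak -> 0 over [t_peak, T]."""
    if not (0 < t_peak_ms < T_ms):
        raise ValueError("t_peak must lie strictly inside (0, T)")
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    t = dt_ms * np.arange(_n_samples(T_ms, dt_ms))
    v = np.where(t <= t_peak_ms,
                 peak * t / t_peak_ms,
                 peak * (T_ms - t) / (T_ms - t_peak_ms))
    return Signal(0.0, dt_ms, np.maximum(v, 0.0))


def gen_spike_train(rate_hz: float, t_on_ms: float, t_off_ms: float) -> SpikeTrain:
    """Regular train at ``rate_hz`` on the half-open interval [t_on, t_off)."""
    if rate_hz < 0:
        raise ValueError("rate must be non-negative")
    if t_off_ms <= t_on_ms:
        raise ValueError("t_off must exceed t_on")
    if rate_hz == 0:
        return SpikeTrain(np.empty(0))
    isi = 1000.0 / rate_hz
    n = int(np.floor((t_off_ms - t_on_ms) / isi))
    times = t_on_ms + isi * np.arange(n + 1)
    return SpikeTrain(times[times < t_off_ms])


LENGTH_MODES = ("isometric", "isokinetic_ramp", "step_shortening",
                "locomotor_sinusoid")


def gen_length_profile(mode: str, params: dict, T_ms: float,
                       dt_ms: float) -> Signal:
    """Muscle-tendon length trajectory X_m (mm; 0 = physiological maximum).

    Modes and required params:

    - ``isometric``: {length}
    - ``isokinetic_ramp``: {start, end, t_start, t_end} (linear ramp)
    - ``step_shortening``: {start, step, t_step} (instantaneous shortening)
    - ``locomotor_sinusoid``: {offset, amplitude, freq_hz} (e.g. ~5 Hz for
      cat locomotion)
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    t = dt_ms * np.arange(_n_samples(T_ms, dt_ms))

    def need(*keys):
        missing = [k for k in keys if k not in params]
        if missing:
            raise ValueError(f"mode {mode!r} missing parameters {missing}")

    if mode == "isometric":
        need("length")
        v = np.full(t.size, float(params["length"]))
    elif mode == "isokinetic_ramp":
        need("start", "end", "t_start", "t_end")
        s, e = float(params["start"]), float(params["end"])
        t0, t1 = float(params["t_start"]), float(params["t_end"])
        v = np.interp(t, [0.0, t0, t1, T_ms], [s, s, e, e])
    elif mode == "step_shortening":
        need("start", "step", "t_step")
        v = np.full(t.size, float(params["start"]))
        v[t >= float(params["t_step"])] += float(params["step"])
    elif mode == "locomotor_sinusoid":
        need("offset", "amplitude", "freq_hz")
        v = (float(params["offset"]) + float(params["amplitude"])
             * np.sin(2e-3 * np.pi * float(params["freq_hz"]) * t))
    else:
        raise ValueError(f"unknown length mode {mode!r}")
    return Signal(0.0, dt_ms, v)


def ou_noise(n: int, dt_ms: float, sd: float, tau_ms: float,
             rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean exponentially correlated noise.

    Exact discretization: lag-1 autocorrelation is exp(-dt/tau) and the
    stationary standard deviation is ``sd`` for any dt.
    """
    if sd < 0:
        raise ValueError("noise sd must be non-negative")
    if sd == 0:
        return np.zeros(n)
    rho = np.exp(-dt_ms / tau_ms)
    x = np.empty(n)
    eps = rng.standard_normal(n)
    x[0] = sd * eps[0]
    s = sd * np.sqrt(1.0 - rho * rho)
    for k in range(1, n):
        x[k] = rho * x[k - 1] + s * eps[k]
    return x


def gen_synaptic_drive(excitation_profile: Signal, scheme: str,
                       g_i_base: float, noise_sd: float = 0.0,
                       noise_tau_ms: float = 20.0, seed: int = 0,
                       balanced_ratio: float | None = None) -> SynapticDrive:
    """Build the inhibitory partner of an excitatory conductance waveform.

    - ``constant_inhibition``: g_i = g_i_base (background inhibition)
    - ``balanced``: g_i = ratio * g_e (co-varying inhibition)
    - ``push_pull``: g_i = g_i_base * (1 - g_e / max(g_e)) -- inhibition
      falls as excitation rises (reciprocal inhibition)

    Independent noise realizations are added to both channels and the
    results are clipped at zero; the same seed yields the same drive.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be non-negative")
    if g_i_base < 0:
        raise ValueError("g_i_base must be non-negative")
    ge = excitation_profile.values
    if np.any(ge < 0):
        raise ValueError("excitation profile must be non-negative")
    if scheme == "constant_inhibition":
        gi = np.full(ge.size, g_i_base)
    elif scheme == "balanced":
        ratio = config.BALANCED_RATIO if balanced_ratio is None else balanced_ratio
        gi = ratio * ge
    elif scheme == "push_pull":
        peak = ge.max()
        gi = g_i_base * (1.0 - ge / peak) if peak > 0 else np.full(ge.size, g_i_base)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    dt = excitation_profile.dt
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        ge = ge + ou_noise(ge.size, dt, noise_sd, noise_tau_ms, rng)
        gi = gi + ou_noise(gi.size, dt, noise_sd, noise_tau_ms, rng)
    ge = np.maximum(ge, 0.0)
    gi = np.maximum(gi, 0.0)
    return SynapticDrive(Signal(excitation_profile.t0, dt, ge),
                         Signal(excitation_profile.t0, dt, gi),
                         scheme=scheme, noise_sd=noise_sd,
                         noise_tau=noise_tau_ms, seed=seed)
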