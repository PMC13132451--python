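# neuromuscle

Population modeling and simulation of the neuromuscular system's primary
cells — spinal motoneurons (MN), muscle–tendon fibers (MT), and the motor
units (MU) they form — at single-cell resolution, with an *inverse*
construction layer: model parameters are determined directly from
experimentally measurable cell properties instead of being fitted to
response time courses.

It is written for computational neuroscientists and biomechanists who
want to ask how the heterogeneity and organization of motoneurons and
muscle fibers shape a muscle's input–output behavior — firing patterns,
force production, and intramuscular EMG — under realistic stimulation
protocols.

## What it implements

- **Motoneuron**: a conductance-based two-compartment cell (soma +
  lumped dendrite coupled by one conductance).  The soma carries fast
  Na⁺, delayed-rectifier K⁺, Ca²⁺-dependent K⁺, persistent Na⁺, and
  N-type Ca²⁺ currents with a Nernstian calcium reversal; the dendrite
  carries the L-type Ca²⁺ persistent inward current (PIC) that produces
  plateau potentials, bistable firing, and counterclockwise firing
  hysteresis.
- **Muscle–tendon fiber**: three modules in series — spike-triggered
  calcium release (two-exponential transients with length-dependent
  amplitude), a dynamic calcium→activation sigmoid (whose drifting
  half-point produces slow/fast differences such as sag), and Hill
  mechanics: contractile element with Gaussian force–length and
  Hill/Mashima force–velocity curves in series with a linear elastic
  element.  Each fiber also synthesizes its motor-unit action potential
  (MUAP) train.
- **Motor unit**: one-to-one spike transmission through an axon with
  finite conduction velocity (pure delay).
- **Inverse layer**: `RMP = f⁻¹(CP)` — closed-form inversion of the five
  passive motoneuron properties (R_N, τ_m, three voltage-attenuation
  factors), lookup-table + live-refinement inversion of rheobase, AHP
  duration, and PIC magnitude, and staged inversion of the fiber
  (twitch dynamics → length dependence → calcium–force relation → Hill
  curves → stiffness).  `CP = g(CI)` — correlation curves keyed by one
  cell indicator (R_N for MN/MU pools, P_0.5 for fiber pools), loaded
  from user-replaceable CSVs.
- **Engine**: embarrassingly parallel pool execution with bit-identical
  serial and local-parallel backends, exact-sum total force and
  intramuscular EMG (iEMG), RMS envelopes, Hann-smoothed firing rates,
  and iEMG–force curvature analysis.

In the standard notation: for each cell *i* of a pool,
`CP_i = g(CI_i)` and `RMP_i = f⁻¹(CP_i)`, where the cell indicator CI is
the somatic input resistance R_N (motoneurons, motor units) or the peak
isometric force P₀.₅ at the intermediate muscle–tendon length (fibers).

## Worked example

Drive the fatigue-resistant (FR) motoneuron preset with the slow
triangular current ramp at the configured 450%-Ia-equivalent amplitude
(16.5 nA peak over 22 s):

```python
from neuromuscle import config, io, motoneuron as mn, protocols as pr

rmp, cmp = io.load_preset("MN", "FR")
sig = pr.triangular_current(config.IA450_CURRENT_NA, 22000.0)
tr = mn.simulate_mn(rmp, cmp, i_soma=sig)
print(f"spikes: {tr.spike_times.size}")
print(f"peak firing rate: {tr.rates.max():.1f} Hz")
print(f"recruitment current: {sig.at(tr.spike_times[0]):.1f} nA")
print(f"derecruitment current: {sig.at(tr.spike_times[-1]):.1f} nA")
```

prints

```
spikes: 530
peak firing rate: 69.9 Hz
recruitment current: 15.2 nA
derecruitment current: 0.0 nA
```

The cell is recruited at 15.2 nA on the ascending ramp, accelerates to a
peak rate of ~70 Hz as the dendritic PIC fully activates, and keeps
firing on the descending ramp all the way to ~0 nA — the
counterclockwise hysteresis (recruitment current ≫ derecruitment
current) that signals PIC-mediated self-sustained firing.  Setting
`g_cal_d = 0` in the preset removes the PIC and closes the loop.

Building and running a heterogeneous 10-unit motor-unit pool under noisy
push–pull synaptic drive is a few more lines:

```python
import numpy as np
from neuromuscle import engine as eng, inverse as inv, protocols as pr

ci = inv.ci_rank_distribution(10, 1.15, 3.35, gamma=1.0)  # R_N per cell
pool = inv.build_population(inv.PopulationSpec("MU", ci))
drives = pr.pool_synaptic_drives(10, "push_pull", T_ms=20000.0, seed=1)
res = eng.run_pool(pool, drives, backend="serial")
print(res.total_force.max(), res.rms_envelope().max())
```

`pool.provenance` holds the per-cell record (CI → CPs → RMPs) for
plotting parameter distributions.  The same scenarios are reachable from
the shell through the `neuromuscle` command (`create-pool`, `gen-signal`,
`run`, `plot-params`, `plot-results`, `fixtures`).

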