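# Methods

`neuromuscle` simulates populations of spinal motoneurons (MNs),
muscle–tendon fibers (MTs), and motor units (MUs) at single-cell
resolution, and constructs heterogeneous populations *inversely*: model
parameters are determined from experimentally measurable cell properties
(CPs) rather than fitted to response time courses.  This note documents
the models, the numerical choices, and what the shipped defaults do and do
not represent.

## Motoneuron model

A conductance-based two-compartment cell: a soma and a lumped dendrite
coupled by a single conductance `G_C` (referenced to total membrane area;
compartment areas are constants).  The soma carries five active currents —
fast Na⁺ (`G_Naf_S`, m³h), delayed-rectifier K⁺ (n⁴), Ca²⁺-dependent K⁺
(saturating in somatic Ca²⁺), persistent Na⁺ (instantaneous, 0 by
default), and an inactivating N-type Ca²⁺ current whose Ca²⁺ reversal
follows the Nernst relation as somatic Ca²⁺ accumulates.  The dendrite
carries the L-type Ca²⁺ current that produces the persistent inward
current (PIC), scaled by the neuromodulatory factor `S_nm`, plus an
optional dendritic Ca²⁺-dependent K⁺ current (0 by default, giving zero
PIC decay).  Somatic calcium obeys
`dCa/dt = f_S · (−α·I_Ca − k_Ca·(Ca − Ca_rest))`: the free-to-bound
fraction `f_S` scales both influx and clearance, so larger `f_S` shortens
the afterhyperpolarization (AHP) — the handle used for spike–twitch
matching across cell types.

All rate-function constants (half-activation voltages, slopes, time
constants) are carried in the constant-parameter (CMP) tables, not in
code, so the kinetics of a preset are fully specified by its CSV.  The
shipped presets (FR, S, FF) are *representative* adult-cat-like cells
calibrated within this kinetic family — input resistance 1.3–2.8 MΩ,
rheobase 15–20 nA, AHP half-durations 28–71 ms, PIC magnitudes 19–23 nA —
not transcriptions of any published parameter file.

Two calibration points of the somatic kinetics deserve note.  The Na⁺
inactivation half-voltage (−50 mV) and a slow calcium clearance
(`k_Ca` = 1/ms) were chosen so the repetitive-firing onset is continuous
(SNIC-like): the passive-dendrite cell then shows essentially no firing
hysteresis on slow ramps (≈0.6 nA loop width vs ≈14–15 nA with the PIC),
which keeps on-ramp hysteresis a PIC phenomenon, as the model family
intends.  Second, channel densities are moderate enough that the fixed
integration step resolves the spike (below).

### The 450%-Ia input level

The triangular-ramp protocols are run at a configured input level
representing synaptic excitation at 450% of a full Ia-afferent input.
This level is defined behaviorally — an FR motoneuron with active
dendrites driven at that level fires at up to ~70 Hz — so the package
anchors its two constants to that landmark once:

- `config.IA450_CURRENT_NA = 16.5`: the somatic ramp amplitude at which
  the FR preset's 22-s triangular protocol peaks at 70 Hz.
- `config.IA450_CONDUCTANCE = 0.2124 mS/cm²`: the dendritic excitatory
  conductance that produces the same steady somatic depolarization in the
  passive cell as 16.5 nA injected at the soma (closed-form two-node
  solve; the conductance also loads the cell, which the solve accounts
  for).

With these, the FR preset peaks at 69.9 Hz under somatic current and
51.8 Hz under the dendritic route — lower through the dendrite because
synaptic drive saturates (driving force and attenuation), the behavior
the protocol is meant to expose.

### Measurement protocols

- **Passive CPs** (input resistance `R_N`, time constant `τ_m`, the three
  voltage-attenuation factors): closed-form two-node circuit/eigenvalue
  expressions, cross-checked on demand against adaptive-step integration
  of DC-step and 100-Hz sinusoidal protocols (the AC attenuation factor is
  defined at 100 Hz).
- **Rheobase**: minimal 500-ms step current eliciting ≥1 spike.  Because
  the set of spiking amplitudes can be non-contiguous (depolarization
  block at high amplitudes; an accommodation pocket at particular Na⁺
  densities), the bracket is located by an upward 2-nA scan before
  bisecting, which makes the measurement protocol-stable.
- **AHP half-duration**: after a single spike elicited by a brief pulse
  (amplitude escalated until a spike occurs), the time the
  hyperpolarization stays below half its trough amplitude relative to the
  pre-stimulus baseline.
- **PIC properties**: somatic voltage clamp implemented as algebraic
  substitution of the command (no feedback-gain knob).  PIC magnitude is
  the maximal leak-subtracted inward current on the ascending limb of a
  slow triangular command (leak reference: the same clamp with all active
  conductances removed); PIC decay is the fractional decline of the
  inward current over a 4-s depolarized hold (zero without dendritic
  K(Ca)); PIC amplification is the magnitude ratio at the cell's `S_nm`
  versus `S_nm = 1` — sublinear in `S_nm` because the unclamped dendrite
  depolarizes and loses calcium driving force.

## Muscle–tendon fiber model

Three modules in series on a shared grid.

**Module 1 — calcium release.**  Each arriving impulse launches a
two-exponential free-calcium transient (rise `τ₁`, fall `τ₂`; peak time
`ln(τ₂/τ₁)·τ₁τ₂/(τ₂−τ₁)`), linearly superposed and normalized to unit
single-twitch peak at the intermediate muscle–tendon length
(X_m,0.5 = −8 mm; lengths are ≤ 0 with 0 the physiological maximum).  The
transient amplitude carries the length dependence: a factor
`exp(φ₁·(X_m−X_{m,0.5}))` below the intermediate length and
`exp(φ₃·(X_m−X_{m,0.5}))` above it (unity at −8 mm).

**Module 2 — activation.**  A Hill sigmoid `Ca^c2/(Ca^c2 + c1^c2)` whose
half-point `c1(t)` and steepness `c2(t)` relax from initial values toward
saturation limits while calcium is elevated (time constants `c1n4`,
`c2n4`); in fast fibers the rising half-point produces sag during unfused
tetani.  Activation is attenuated under fluctuating calcium by
`1/(1+α_i·fluct)` with `fluct` the normalized deviation of calcium from
its 150-ms moving average (zero in a fused tetanus, so full activation is
preserved), and by a movement factor
`max(0, 1 − β·|ΔX_CE| − γ·|V_CE|)`; with `β = γ = 0` module 2 is exactly
independent of the mechanics.

**Module 3 — Hill mechanics.**  A contractile element (CE) in series with
a linear elastic element (stiffness `K_SE`, clipped at zero force when
slack).  Active CE force is `scale(P_0.5)·A·fl(X_CE)·fv(V_CE)` with a
Gaussian force–length curve `exp(−((X_CE−g₁)/g₂)²)` and a two-branch
force–velocity factor: Hill hyperbola `(b₀−a₀·s)/(b₀+s)` for shortening
speed `s`, Mashima form `(c₀+d₀·v)/(c₀+v)` for lengthening speed `v`,
continuous with `fv(0)=1` by construction.  Each step inverts `fv` in
closed form at the current force ratio to obtain the CE velocity
(operator splitting: calcium → activation → mechanics).  When the fiber
is nearly inactive the inversion degenerates; the CE then follows the
imposed length at a capped velocity so the series element stays slack —
this replaces an error path that would otherwise fire on every resting
fiber.  The maximal CE force is calibrated in closed form at construction
so the fully excited isometric force at the intermediate length equals
`P_0.5` exactly (`P_0.5` is an observable, not a gain).

**MUAP synthesis.**  One first-order Hermite–Rodriguez biphasic waveform
(zero-mean by antisymmetry) of amplitude `A_MUAP` and support `L_MUAP`
per impulse, shifted by the axonal conduction delay and linearly
superposed; intramuscular EMG is the exact sum over fibers.

The slow (SOL) and fast (MG) presets give twitch contraction times of
~70 and ~22 ms, twitch/tetanus ratios ≈ 0.17, and peak forces rising with
length over the full operating range (the force–length peak sits near the
physiological maximum), matching the qualitative battery: isolated
twitches at 1 Hz, monotone force–frequency over 1–100 Hz, shortening <
isometric < lengthening force at full excitation, quick-release drop and
recovery, and ~5-Hz locomotor-like length modulation.

## Motor unit

One motoneuron drives one lumped fiber through an axon that transmits
every somatic spike with delay `axon_length/CV` (one-to-one, no failures;
spikes whose delayed arrival falls beyond the simulation window are
dropped).  The conduction distance (100 mm) is a constant; `CV` is the
cell-varying parameter.  Spike–twitch matching arises through the
correlation layer: the same cell indicator sets `f_S` (AHP duration) and
`τ₁, τ₂` (twitch speed).

## Inverse layer

`RMP = f⁻¹(CP)` proceeds in the stages the forward measurements define:

1. **Passive (closed form).**  The two DC attenuation factors fix the
   conductance ratios, `R_N` fixes the scale; the dendritic capacitance
   follows from the AC attenuation, and the somatic capacitance is the
   1-D root of the slowest-eigenvalue condition for `τ_m`.  Round trips
   are exact to ~1e-13; infeasible combinations (e.g. AC attenuation not
   below DC, or a `τ_m` no capacitance can reach) are refused with the
   violated constraint named.
2. **Somatic active (lookup + live refinement).**  `(I_rheo, t_AHP1/2)`
   maps to `(G_Naf_S, f_S)` through a forward-measured grid (default
   21×21 over G_Naf_S ∈ [30, 52] mS/cm², f_S ∈ [0.01, 0.06]) validated
   for monotonicity, then refined per cell by bracketed bisection against
   live measurement (alternating the two axes, which are nearly
   decoupled).  The G_Naf_S cap marks the validity range: above ~52–55
   the first-spike current set develops a non-monotone pocket.  Pool-wide
   round trips under live re-measurement are ≤1%.
3. **PIC (1-D lookup).**  PIC magnitude fixes the effective conductance
   `S_nm·G_Cal_D`; the amplification ratio then splits it into `S_nm` and
   `G_Cal_D` through the tabulated magnitude curve.  Without PIC targets
   the defaults are `G_Cal_D = 0`, `G_KCa_D = 0`, `S_nm = 1`.
4. **Fiber (staged, module order).**  `τ₁, τ₂` by nested bracketed
   root-finds matching the simulated twitch contraction and
   half-relaxation times (bracketing is used because the measured times
   are quantized to the integration grid); `φ₁, φ₃` by 1-D root-finds on
   the twitch-amplitude ratios at −16 and 0 mm; the calcium–force and
   degradation coefficients are the fiber's own CPs (direct); `g₁, g₂`
   and the four force–velocity coefficients in closed form from the curve
   features; `K_SE` direct; `P_0.5` exact by the construction-time
   calibration.  Each stage validates by forward simulation (default 2%).

`CP = g(CI)` is a set of named curves (linear, exponential decay,
piecewise with jumps, tabulated, constant) keyed by the cell indicator —
`R_N` for MN/MU pools, `P_0.5` for MT pools — loaded from CSV so
experimental correlation sets can replace the defaults wholesale or per
curve (e.g. swapping the twitch-speed relation for an exponentially
decaying one).

**Shipped correlation tables are synthetic placeholders.**  They are
tabulated through the forward-measured CPs of the three MN presets plus
two endpoint cells obtained by pure conductance scaling (R_N 1.08 and
3.40 MΩ), which guarantees that every interpolated CP target is jointly
feasible for the model family; the fiber curves interpolate the SOL and
MG presets with an exponentially decaying twitch-time–force relation, and
MU pools link the two sides through an inverse exponential R_N–P_0.5 map
and a linear P_0.5–CV map.  The fast/slow AHP discontinuity is placed at
R_N = 2.2 MΩ.  D_path (soma-to-PIC path length) maps to a PIC
half-activation shift of 8 mV/mm about the 0.6-mm reference — a
documented placeholder for the anatomical distribution.

`build_population` composes the layers deterministically (no hidden
randomness); any per-cell failure aborts with the cell index and stage,
and a provenance table records CI, CPs, and RMPs per cell.  Lookup tables
are memoized per constant-parameter preset (they are pure functions of
it).

## Engine

Cells are pure functions of (parameters, drive, per-cell seed), so pools
run embarrassingly parallel.  The serial and local-parallel (joblib)
backends are bit-identical for any worker count because every cell
computes identically and aggregation always sums in cell-index order.
Total force and iEMG are exact elementwise sums; the iEMG envelope is a
centered 100-ms moving RMS; mean pool rate averages Hann-smoothed
(0.5 s) per-cell instantaneous rates over cells with ≥2 spikes.  The
iEMG–force relation discards the first 0.5 s (force-development lag),
normalizes both channels to their maxima, and summarizes curvature as the
signed area between the force-vs-iEMG curve and the identity: 0 linear,
negative superlinear (force lags iEMG), positive sublinear.

### Pool scenario conditions

The population scenarios drive each motoneuron's dendrite with a
triangular excitatory conductance under one of three inhibition schemes —
constant background, balanced (`g_i = 0.5·g_e`), or push–pull
(`g_i = g_i_base·(1−g_e/max g_e)`) — plus exponentially correlated
(Ornstein–Uhlenbeck) conductance noise (SD 0.01 mS/cm², correlation time
20 ms; exact discretization, clipped at zero, reproducible per seed).
The ramp peak (0.2 mS/cm²) is sized so that all units of the default
pools are recruited comfortably within the ascending phase while
recruitment stays staggered across it (about twice the highest
recruitment threshold).  This sizing matters: with the placeholder
correlations the recruitment-threshold span is narrower than in cat data,
and a much stronger drive saturates every unit early, inverting the
organization-dependence of the mean firing rate.  The 40-nA triangular
somatic ramp (peak at 5 s over 10 s) with passive dendrites is the
fixed-drive protocol for the muscle-length analyses.

## Numerics

- Fixed-step 4th-order Runge–Kutta on a 0.1-ms output grid; the
  motoneuron integrator takes 2 internal substeps per sample so the Na⁺
  upstroke stays resolved (inputs are sample-and-hold on the output
  grid).  Halving the step leaves spike counts unchanged and early spike
  times within 1 ms; late spikes accumulate only a slow phase drift.
- Voltages entering rate functions are clamped to ±150 mV so a diverging
  trajectory reaches the caller's detection (|V| > 500 mV aborts with the
  blow-up time) instead of overflowing.
- Gating variables are clipped to [0,1] and calcium to ≥0 against
  round-off; fiber module-1 states decay by exact exponentials.
- Root-finding: `brentq` with bracket-location scans wherever the
  measured quantity is grid-quantized or the landscape may be
  non-monotone; interpolation at exact grid nodes returns node values.

Problem sizes of the shipped analyses: single-cell protocols run 13–22 s
of model time; the pool analyses use 10-unit pools for the 20-s
aggregation scenario and 20-unit pools for the organization and
muscle-length analyses (5 organization shapes are provided; three —
S-dominant, linear, F-dominant — are exercised by default).

## What the synthetic defaults do and do not show

The generator-level defaults emulate the *structure* of adult-cat
neuromuscular organization: continuous heterogeneity indexed by one cell
indicator, fast/slow type boundaries, inverse size relations between
excitability and force, and spike–twitch speed matching.  They do not
carry the quantitative cat correlations (those live in replaceable CSVs),
fatigue, potentiation, history-dependent force effects, afferent
feedback, or closed-loop recurrent inhibition; muscle fibers within a
unit activate synchronously (asynchrony can be emulated by pools of
identical cells differing only in CV).  Passing tests therefore show that
the inverse machinery, the cell models, and the population analyses are
internally consistent and reproduce the qualitative input–output
phenomena — not that the shipped numbers match any particular animal's
data.

## Known limitations

- Inversion accuracy for rheobase degrades to a few percent for cells
  whose targets fall at the edge of the G_Naf_S validity band.
- The somatic model's repetitive-firing range starts near 12 Hz; very low
  tonic rates (<10 Hz) are outside the shipped kinetics.
- PIC amplification is sublinear in `S_nm` (voltage feedback), so
  `PIC_amp` targets above ~2 are refused by the bracketed solve.
- The organization-dependent mean-rate result is sensitive to the drive
  amplitude relative to the recruitment span (see Pool scenario
  conditions).
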