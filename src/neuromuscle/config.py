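"""Package-wide configuration constants.

Time is in milliseconds throughout, voltages in mV, currents in nA,
conductance densities in mS/cm2, lengths in mm, forces in N.  Signals are
sample-and-hold between grid points and t = 0 is the simulation start.
"""

#: Default integration step (ms).  All protocol batteries in the package are
#: run at this resolution; halving it changes spike times by well under a
#: millisecond (see the convergence test).
DT_MS = 0.1

#: Spike detection: upward crossing of this somatic voltage (mV) with the
#: given refractory interval (ms).
SPIKE_THRESHOLD_MV = 0.0
SPIKE_REFRACTORY_MS = 1.0

#: Somatic current (nA) equivalent to synaptic excitation at 450% of the
#: full Ia-afferent input of a reconstructed FR-type motoneuron.  The value
#: is anchored to the behavioral landmark reported for that input level --
#: an FR motoneuron with active dendrites firing at up to ~70 Hz -- by
#: choosing the ramp amplitude at which the shipped FR preset's slow
#: triangular protocol peaks at 70 Hz (see docs/methods.md).  Exposed here,
#: not hard-coded in protocol builders, because it is a calibration constant.
IA450_CURRENT_NA = 16.5

#: Peak dendritic excitatory conductance (mS/cm2) delivering the same input
#: level through the synaptic route: the conductance that produces the same
#: steady somatic depolarization in the passive cell as IA450_CURRENT_NA
#: injected at the soma (closed-form two-node circuit solve; see
#: docs/methods.md).
IA450_CONDUCTANCE = 0.2124

#: Excitatory / inhibitory synaptic reversal potentials (mV).
E_ESYN_MV = 0.0
E_ISYN_MV = -75.0

#: Balanced-inhibition scheme: g_i = BALANCED_RATIO * g_e.
BALANCED_RATIO = 0.5

#: Conduction distance from the soma to the muscle unit (mm); the axonal
#: conduction velocity is the cell-varying parameter, the distance is not.
AXON_LENGTH_MM = 100.0

#: Aggregation defaults: moving-RMS window for iEMG envelopes and Hann
#: window for smoothing instantaneous firing rates.
RMS_WINDOW_MS = 100.0
HANN_WINDOW_MS = 500.0

#: Delay (ms) in force development discarded before computing EMG-force
#: relations.
EMG_FORCE_ONSET_DELAY_MS = 500.0

#: Intermediate muscle-tendon length (mm, 0 = physiological maximum).
XM_INTERMEDIATE_MM = -8.0
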