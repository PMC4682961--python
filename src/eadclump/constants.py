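"""Versioned default parameter values shared across the package."""

#: myocyte membrane capacitance, pF
CM_MYOCYTE = 185.0

#: fibroblast membrane capacitance, pF
CF_FIBROBLAST = 6.3

#: fibroblast membrane conductance (constant model), nS
GF_FIBROBLAST = 4.0

#: piecewise fibroblast conductance: value below / at-or-above the breakpoint, nS
GF_PIECEWISE_LOW = 2.0
GF_PIECEWISE_HIGH = 4.0
GF_BREAKPOINT_MV = -20.0

#: default myocyte-fibroblast gap-junctional conductance, nS
GGAP_DEFAULT = 8.0

#: tissue diffusion constant, cm^2/ms (the cm^2/ms reading is the one
#: consistent with a 65 cm/s planar conduction velocity at dx = 0.02 cm)
D0 = 0.0012

#: spatial resolution, cm (one grid point = one cell)
DX = 0.02

#: temporal resolution, ms
DT = 0.02

#: tissue stimulus amplitude, uA/uF (negative = depolarizing under the
#: sign convention dV/dt = -(I_ion + I_gap/C_m + I_stim) + D lap(V))
STIM_AMPLITUDE = -150.0

#: tissue stimulus pulse duration, ms
STIM_DURATION = 3.0

#: single-cell stimulus pulse duration, ms (same amplitude as tissue; the
#: 3 ms tissue pulse is unphysiological without a diffusive load)
STIM_DURATION_CELL = 0.5

#: default time of the first pacing pulse, ms
FIRST_PULSE_MS = 50.0

#: EAD parameter sets: conductance multipliers relative to control
GCAL_EAD = 4.0
GKR_TYPE1 = 0.21
#: type-II G_Kr multiplier (chosen by scanning downward from the type-I
#: value until the AP shows decaying EADs that relax to an elevated
#: potential instead of repolarizing)
GKR_TYPE2 = 0.12

#: default trace sampling interval, ms
SAMPLE_MS = 1.0
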