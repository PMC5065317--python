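# Two-conductance + leak model of the R205H proton channel variant:
# a hyperpolarization-activated shuttle conductance (SH), the intrinsic
# depolarization-activated aqueous conductance (AQ), and ohmic leak.
# Units: nS, mV, ms; v_half values refer to extracellular pH 6.5.
conditions:
  ph_i: 6.5
  ph_o: 6.5
  temperature: 293.15
conductances:
  - label: SH
    g_max: 4.6
    v_half: -189.0
    slope_dx: 42.1
    polarity: hyperpolarization
    tau_act: 5.0
    tau_deact: 3.0
    ph_shift_slope: -40.0
  - label: AQ
    g_max: 22.2
    v_half: 29.4
    slope_dx: 24.9
    polarity: depolarization
    tau_act: 20.0
    tau_deact: 10.0
    ph_shift_slope: -40.0
  - label: LEAK
    g_max: 1.5
    is_ohmic: true
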