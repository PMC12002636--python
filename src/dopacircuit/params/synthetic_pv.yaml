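# Synthetic parameter set for the fast-spiking parvalbumin (PV) interneuron.
# Constructed and calibrated for this package (not transcribed from any
# published supplement): a point neuron with transient Na, delayed-rectifier
# K and a fast A-type K conductance, tuned for narrow spikes and high
# sustained firing rates.  Units: C_m nF, g uS, E mV, tau ms.
type: PV
soma: soma
compartments:
  - id: soma
    C_m: 0.05
    V_init: -65.0
    multiplicity: 1
    channels:
      - name: Na
        g_max: 3.5
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -55.0, k: -6.5, tau_min: 0.25, tau_amp: 4.0, tau_vhalf: -55.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 1.6
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.3, tau_amp: 3.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: KA
        g_max: 0.02
        E_rev: -90.0
        gates:
          - {name: a, exponent: 1, v_half: -45.0, k: 12.0, tau_min: 1.0, tau_amp: 4.0, tau_vhalf: -50.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: leak
        g_max: 0.010
        E_rev: -65.0
        gates: []
coupling: []
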