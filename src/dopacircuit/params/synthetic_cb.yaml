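# Synthetic parameter set for the calbindin (CB) interneuron.  Constructed
# and calibrated for this package: a point neuron with transient Na,
# delayed-rectifier K and a hyperpolarization-activated cation (H) current,
# distinguishing it from the fast-spiking PV class.
# Units: C_m nF, g uS, E mV, tau ms.
type: CB
soma: soma
compartments:
  - id: soma
    C_m: 0.06
    V_init: -65.0
    multiplicity: 1
    channels:
      - name: Na
        g_max: 3.0
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -52.0, k: -5.0, tau_min: 0.3, tau_amp: 5.0, tau_vhalf: -55.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 1.1
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.4, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: H
        g_max: 0.02
        E_rev: -30.0
        gates:
          - {name: m, exponent: 1, v_half: -75.0, k: -8.0, tau_min: 80.0, tau_amp: 200.0, tau_vhalf: -75.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: leak
        g_max: 0.012
        E_rev: -72.0
        gates: []
coupling: []
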