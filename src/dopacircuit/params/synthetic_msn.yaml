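# Synthetic parameter set for the NAc medium spiny neuron (MSN, D2-type).
# Constructed and calibrated for this package: one soma plus ten identical
# dendrites.  The dendrites are identical in parameters and inputs, so a
# single representative dendritic compartment is integrated with
# multiplicity 10.  The slowly inactivating A-type K (KAs) and L-type Ca
# (CaL1.2) conductances are the dopamine-sensitive (D2) conductances.  The
# hyperpolarized leak reversal emulates the strong inward rectification that
# holds MSNs in their down-state near -80 mV.
# Units: C_m nF, g uS, E mV, tau ms.
type: MSN
soma: soma
compartments:
  - id: soma
    C_m: 0.10
    V_init: -75.0
    multiplicity: 1
    channels:
      - name: Na
        g_max: 4.5
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -45.0, k: -7.0, tau_min: 0.3, tau_amp: 5.0, tau_vhalf: -45.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 2.6
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.8, tau_amp: 6.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: KAs
        g_max: 0.10
        E_rev: -90.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -45.0, k: 10.0, tau_min: 25.0, tau_amp: 60.0, tau_vhalf: -50.0, tau_s1: 20.0, tau_s2: 20.0}
          - {name: h, exponent: 1, v_half: -40.0, k: -10.0, tau_min: 100.0, tau_amp: 300.0, tau_vhalf: -55.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: CaL1.2
        g_max: 0.02
        E_rev: 120.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -25.0, k: 6.0, tau_min: 1.5, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 15.0, tau_s2: 15.0}
      - name: leak
        g_max: 0.012
        E_rev: -75.0
        gates: []
  - id: dendrite
    C_m: 0.035
    V_init: -75.0
    multiplicity: 10
    channels:
      - name: Na
        g_max: 0.6
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -45.0, k: -7.0, tau_min: 0.3, tau_amp: 5.0, tau_vhalf: -45.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 0.3
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.8, tau_amp: 6.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: KAs
        g_max: 0.05
        E_rev: -90.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -45.0, k: 10.0, tau_min: 25.0, tau_amp: 60.0, tau_vhalf: -50.0, tau_s1: 20.0, tau_s2: 20.0}
          - {name: h, exponent: 1, v_half: -40.0, k: -10.0, tau_min: 100.0, tau_amp: 300.0, tau_vhalf: -55.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: CaL1.2
        g_max: 0.012
        E_rev: 120.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -25.0, k: 6.0, tau_min: 1.5, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 15.0, tau_s2: 15.0}
      - name: leak
        g_max: 0.002
        E_rev: -75.0
        gates: []
coupling:
  - {a: soma, b: dendrite, g_c: 0.02, count: 10}
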