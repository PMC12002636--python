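# Synthetic parameter set for the mPFC pyramidal neuron (D1-type).
# Constructed and calibrated for this package: three compartments (soma,
# proximal dendrite, distal dendrite).  The soma carries fast spiking
# conductances plus a high-voltage-activated Ca channel; the proximal
# dendrite carries the persistent Na (NaP) and slow K (KS) conductances that
# set excitability; the distal dendrite carries an N-type Ca (Can)
# conductance.  Ca, Can, KS and NaP are the dopamine-sensitive (D1)
# conductances.  Units: C_m nF, g uS, E mV, tau ms.
type: Pyra
soma: soma
compartments:
  - id: soma
    C_m: 0.10
    V_init: -65.0
    multiplicity: 1
    channels:
      - name: Na
        g_max: 4.0
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -55.0, k: -6.5, tau_min: 0.3, tau_amp: 5.0, tau_vhalf: -55.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 1.7
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.4, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: Ca
        g_max: 0.06
        E_rev: 120.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 2, v_half: -25.0, k: 7.0, tau_min: 1.0, tau_amp: 3.0, tau_vhalf: -30.0, tau_s1: 15.0, tau_s2: 15.0}
      - name: leak
        g_max: 0.010
        E_rev: -66.0
        gates: []
  - id: proximal
    C_m: 0.09
    V_init: -65.0
    multiplicity: 1
    channels:
      - name: Na
        g_max: 1.2
        E_rev: 55.0
        gates:
          - {name: m, exponent: 3, v_half: -38.0, k: 7.0, tau_min: 0.05, tau_amp: 0.25, tau_vhalf: -40.0, tau_s1: 12.0, tau_s2: 12.0}
          - {name: h, exponent: 1, v_half: -55.0, k: -6.5, tau_min: 0.3, tau_amp: 5.0, tau_vhalf: -55.0, tau_s1: 12.0, tau_s2: 12.0}
      - name: Kdr
        g_max: 0.6
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.4, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: NaP
        g_max: 0.008
        E_rev: 55.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -50.0, k: 5.0, tau_min: 0.5, tau_amp: 2.0, tau_vhalf: -50.0, tau_s1: 15.0, tau_s2: 15.0}
      - name: KS
        g_max: 0.10
        E_rev: -90.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 1, v_half: -40.0, k: 9.0, tau_min: 10.0, tau_amp: 50.0, tau_vhalf: -45.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: leak
        g_max: 0.008
        E_rev: -66.0
        gates: []
  - id: distal
    C_m: 0.08
    V_init: -65.0
    multiplicity: 1
    channels:
      - name: Can
        g_max: 0.02
        E_rev: 120.0
        dopamine_sensitive: true
        gates:
          - {name: m, exponent: 2, v_half: -30.0, k: 8.0, tau_min: 1.5, tau_amp: 4.0, tau_vhalf: -35.0, tau_s1: 15.0, tau_s2: 15.0}
      - name: Kdr
        g_max: 0.45
        E_rev: -90.0
        gates:
          - {name: n, exponent: 4, v_half: -30.0, k: 9.0, tau_min: 0.4, tau_amp: 4.0, tau_vhalf: -40.0, tau_s1: 20.0, tau_s2: 20.0}
      - name: leak
        g_max: 0.012
        E_rev: -66.0
        gates: []
coupling:
  - {a: soma, b: proximal, g_c: 0.10, count: 1}
  - {a: proximal, b: distal, g_c: 0.08, count: 1}
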