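# Synthetic dopamine-modulation rules, constructed for this package.
# Each entry is the linear sensitivity slope of a channel family's maximal
# conductance: g_eff = g_max * (1 + slope * (DA - 0.5)), DA in [0, 1].
# D1-type (pyramidal): dopamine boosts the persistent Na and Ca conductances
# and suppresses the slow K conductance, raising excitability with DA.
# D2-type (MSN): dopamine boosts KAs and suppresses CaL1.2, lowering
# intrinsic excitability with DA -- which offsets the growing cortical
# drive so that MSN firing stays roughly level across dopamine conditions.
rules:
  Pyra:
    NaP: 0.3
    KS: -0.3
    Ca: 0.3
    Can: 0.3
  MSN:
    KAs: 0.35
    CaL1.2: -0.35
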