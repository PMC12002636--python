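# Synthetic external stimulus currents, constructed for this package.
# Every neuron receives a constant depolarizing current (nA) injected at its
# soma; amplitudes are population-specific and hold each cell near its
# rheobase so that synaptic input and dopaminergic modulation shape the
# firing pattern.
amplitudes:
  MSN: 2.0
  PV_NAc: 0.25
  CB_NAc: 0.05
  Pyra: 0.36
  PV_mPFC: 0.16
  CB_mPFC: 0.05
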