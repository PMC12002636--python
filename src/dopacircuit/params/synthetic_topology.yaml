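# Synthetic connectivity for the 28-neuron NAc-mPFC microcircuit,
# constructed for this package.  Populations: MSN, PV_NAc, CB_NAc (NAc);
# Pyra (x20), PV_mPFC (x3), CB_mPFC (x2).  Each projection is expanded
# all-to-all between its populations (self-connections excluded); "target"
# names the postsynaptic compartment.  Excitatory projections create one
# AMPA and one NMDA synapse per edge; inhibitory projections one GABAa
# synapse.  g values are per-synapse maximal conductances in uS.
projections:
  # mPFC recurrent excitation and feedforward inhibition
  - {pre: Pyra, post: Pyra, target: proximal, receptors: {AMPA: 0.0008, NMDA: 0.0005}}
  - {pre: Pyra, post: PV_mPFC, target: soma, receptors: {AMPA: 0.0020, NMDA: 0.0010}}
  - {pre: Pyra, post: CB_mPFC, target: soma, receptors: {AMPA: 0.0003, NMDA: 0.0002}}
  - {pre: PV_mPFC, post: Pyra, target: soma, receptors: {GABAa: 0.0040}}
  - {pre: CB_mPFC, post: Pyra, target: distal, receptors: {GABAa: 0.0030}}
  - {pre: PV_mPFC, post: PV_mPFC, target: soma, receptors: {GABAa: 0.0020}}
  - {pre: CB_mPFC, post: CB_mPFC, target: soma, receptors: {GABAa: 0.0020}}
  - {pre: PV_mPFC, post: CB_mPFC, target: soma, receptors: {GABAa: 0.0400}}
  # corticostriatal projections (mPFC -> NAc)
  - {pre: Pyra, post: MSN, target: soma, receptors: {AMPA: 0.0026, NMDA: 0.00155}}
  - {pre: Pyra, post: PV_NAc, target: soma, receptors: {AMPA: 0.00008, NMDA: 0.00005}}
  - {pre: Pyra, post: CB_NAc, target: soma, receptors: {AMPA: 0.00005, NMDA: 0.00003}}
  # NAc feedforward inhibition
  - {pre: PV_NAc, post: MSN, target: soma, receptors: {GABAa: 0.0040}}
  - {pre: CB_NAc, post: MSN, target: soma, receptors: {GABAa: 0.0030}}
  - {pre: PV_NAc, post: CB_NAc, target: soma, receptors: {GABAa: 0.0010}}
  - {pre: CB_NAc, post: PV_NAc, target: soma, receptors: {GABAa: 0.0010}}
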