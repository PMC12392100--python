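# Same circuit with the learning rates interchanged (slow early / fast
# late) plus a signal-dependent perturbation at the full envelope:
# sustained weight-space oscillation between unstable and leaky tunings.
name: interchanged
seed: 7
outdir: results/interchanged
params:
  duration: 4000.0
  mu: 1.0
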