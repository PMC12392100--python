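# Stable-regime tuning of the neural integrator: fast early (cerebellar)
# learning, slow late (recurrent) consolidation, cerebellar inactivation
# probes at mid-learning and after consolidation.
name: consolidation
seed: 7
outdir: results/consolidation
params:
  N: 20
  c_align: 0.9
  lambda0: 1.05
  eta1: 5.0e-3
  eta2: 5.0e-4
  duration: 5000.0
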