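# Empirical convergence labels over the (alpha, mu) grid against the
# certified boundary alpha <= 1 - mu.
name: stability_map
seed: 0
outdir: results/stability_map
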