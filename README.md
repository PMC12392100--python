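# consolidyn

Simulation and Lyapunov-certification toolkit for **two-stage systems
consolidation**: learning architectures in which an early site of
plasticity with direct access to an error signal (a cerebellar-cortex
analog) trains a late storage site that never sees the error itself (a
cerebellar/vestibular-nucleus or neural-integrator analog).

The package answers a concrete question about such circuits: *how fast
may the late stage consolidate before the learning loop itself becomes
unstable?* It is aimed at computational neuroscientists and adaptive-
control practitioners who want reproducible numerical witnesses of the
stability bounds, not just the algebra.

## Models

**Gain-tracking circuit.** Two parallel gains map a command `rin(t)` to
an output `(w1 + w2)·rin`; the target is `w*·rin`. The early gain
follows a delta rule on the (possibly perturbed) tracking error, the
late gain a heterosynaptic rule on the early stage's output:

    dw1/dt = -η₁ rin (e + ξ),   dw2/dt = η₂ rin (w1 rin),
    e = (w1 + w2 - w*) rin,     |ξ| ≤ μ|e|.

With the Lyapunov candidate `L = ½(W̃² + w̃₂²)` (gain error
`W̃ = w1+w2-w*`, consolidation error `w̃₂ = w2-w*`), learning is
provably stable whenever the rate ratio satisfies

    α = η₂/η₁ ≤ α_c = 1 − μ.

Eliminating `w1` maps the circuit onto a forced mass–spring–damper with
damping ratio `ζ = 1/(2√α)`: fast consolidation is low damping, and a
probe perturbation at the natural frequency `ωₙ = √(η₁η₂)` is amplified
by `1/(2ζ) = √α` — above unity exactly when `α > 1`.

**Oculomotor neural integrator.** An N-neuron linear recurrent network
integrates saccadic velocity commands into a persistent eye-position
readout `Ê = d⊤r`; holding fixation requires a unity eigenvalue of the
recurrent matrix `Ω` along the readout. A lumped Purkinje-cell loop
learns the tuning from retinal-slip errors and consolidates it into
`Ω`. The matrix Lyapunov candidate `L = ½‖d⊤W̃‖² + ½‖d⊤Ω̃‖²` yields the
analogous bound

    α ≤ (1 − μ)·c,   c = d⊤k_PC,

where `c` is the cosine between the readout decoder and the cerebellar
projection: the worse the alignment, the slower the late stage must be.

All inputs (commands, saccade trains, perturbation processes) are
generated internally by seeded generators; no external data is needed.

## Worked example

```python
>>> from consolidyn import critical_alpha_toy, critical_alpha_NI, resonance_amplification
>>> critical_alpha_toy(0.2).alpha_critical        # bisection on the L-derivative bound
0.8000000007450581
>>> critical_alpha_NI(0.5, 0.2).alpha_critical    # alignment c = 0.5
0.4000000022351742
>>> resonance_amplification(3.0)                  # closed form, probe at omega_n
1.732050807568877
>>> resonance_amplification(3.0, method="simulation")
1.732050836520879
```

The first two numbers are the certified stability boundaries `1 − μ`
and `(1 − μ)c` at μ = 0.2, recovered numerically (to the 1e-6 bisection
tolerance) from the negative-semidefiniteness of the worst-case
Lyapunov-derivative bound. The last two show that a probe perturbation
at the natural frequency is amplified √3 ≈ 1.73-fold at α = 3 — the
closed-form frequency response and an independent long-horizon forced
integration agree to five decimals.

From the shell:

```sh
$ consolidyn simulate-toy --alpha 0.5 --duration 200
label=converged final_gain_error=1.302e-05 -> toy_trajectory.csv
$ consolidyn simulate-integrator --duration 5000
$ consolidyn run examples/consolidation.yaml
```

Experiments (`single_stage`, `two_stage`, `stability_map`,
`resonance_sweep`, `consolidation`, `interchanged`) write trajectory
CSVs, a `metrics.json` and a config echo; identical config + seed give
byte-identical outputs.

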