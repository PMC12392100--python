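# Methods

## Models

### Two-stage gain-tracking circuit

The circuit tracks a command `rin(t)` with output `(w1 + w2)·rin`.
The early gain `w1` (cerebellar-cortex analog) learns from the
perturbed tracking error, the late gain `w2` (downstream storage
analog) only from the early stage's corrective output `r1 = w1·rin`:

    dw1/dt = -η₁ rin (e + ξ),     e = (w1 + w2 - w*) rin
    dw2/dt =  η₂ rin (w1 rin)

The perturbation `ξ` models corruption of the teaching signal; in the
signal-dependent regime its envelope scales with the error,
`|ξ| ≤ μ|e|`, so it vanishes at the solution and no decay/forgetting
term is needed. Consolidation succeeds when the memory transfers
entirely: `w1 → 0`, `w2 → w*`.

Stability is certified with `L_b = ½(W̃² + b·w̃₂²)` in the gain error
`W̃ = w1 + w2 - w*` and consolidation error `w̃₂ = w2 - w*`. Along
trajectories,

    dL_b/dt = -η₁ rin² [(1-α)W̃² + α(1-b)W̃w̃₂ + αb w̃₂²] - η₁ W̃ rin ξ,

with `α = η₂/η₁`. Replacing `ξ` by its adversarial envelope value
(ξ = -μe, which turns the last term into `+η₁μ rin² W̃²`) leaves a
quadratic form in `(W̃, w̃₂)`; the certificate holds wherever the form's
bracket is positive semidefinite. For the equal weighting `b = 1` the
cross term cancels and the boundary is `α_c = 1 - μ`. For `b ≠ 1` the
cross-term discriminant caps the certificate at
`α_c(μ, b) = 4b(1-μ)/(1+b)² ≤ 1-μ`, with equality only at `b = 1`:
reweighting the two error terms cannot raise the criterion. (We note
this is slightly stronger than the informal claim that any `b > 0`
certifies up to `α = 1`; the implementation reports the
discriminant-correct value, and the ceiling `α_c ≤ 1` always holds.)
The single-stage special case (`dw2/dt = 0`, `L₁ = ½W̃²`) tolerates
perturbations up to `μ = 1`.

Outside the certified region the worst-case derivative bound turns
positive on the wedge `|w̃₂| < √((α-α_c)/α)·|W̃|`; the slope is exposed
by `violation_boundary` and grows toward 1 as `α → ∞`.

### Damped-oscillator reduction

For `rin = 1`, `μ → 0` and a probe `ξ_p = ε sin(ωt)`, eliminating `w1`
gives

    w̃₂'' + η₁ w̃₂' + η₁η₂ w̃₂ = -η₁η₂ ε sin(ωt),

i.e. a unit-mass forced oscillator with damping coefficient `η₁`,
spring constant `η₁η₂`, natural frequency `ωₙ = √(η₁η₂)` and damping
ratio `ζ = 1/(2√α)`. The steady-state amplitude is the standard
frequency response `ε/√((1-ρ²)² + (2ζρ)²)`, `ρ = ω/ωₙ`. At resonance
the amplitude is `ε/(2ζ) = ε√α`. A reading of the resonance amplitude
as `αε` circulates in the consolidation literature; the two coincide
only at `α = 1`. We do not adjudicate algebraically — the package
exposes the closed form *and* an independent brute-force value from a
long forced integration (`resonance_amplification(..., method=
"simulation")`); both give `√α·ε` (agreement ~1e-8 relative), and
both readings share the headline threshold: amplification exceeds the
probe exactly when `α > 1`.

The reduction is exact for the linear circuit: the two-stage simulation
and the second-order integration are related by an invertible linear
change of variables (`x = w̃₂`, `x' = η₂ w1 rin²`), so matched
fixed-step runs coincide to machine precision (RMS ≈ 1e-15 observed;
the acceptance test requires 1e-6).

### Neural integrator with cerebellar loop

An N-neuron linear network (nondimensionalized by the neuronal time
constant τ) with readout `Ê = d⊤r`:

    dr/dt   = -r + Ωr - k_PC (w_PC⊤ r) + k_sacc·I_sacc
    dw_PC/dt = η₁ (ė + ξ) r
    dΩ/dt    = -η₂ k_PC (w_PC⊤r) r⊤

Retinal slip rate: `ė = -(d⊤W̃)r` with `W̃ = k_PC w_PC⊤ + I - Ω` (the
saccadic pathway is calibrated so `d⊤k_sacc = 1`, killing the command
term). The matrix candidate `L = ½‖d⊤W̃‖² + ½‖d⊤Ω̃‖²` uses only the
readout projections; since any acceptable target matrix satisfies
`d⊤Ω* = d⊤`, the detuning row `d⊤Ω̃ = d⊤Ω - d⊤` is independent of the
choice of `Ω*`. The derivative collapses to scalars,

    dL/dt = -η₁ [ (c-α) ė² + c ξ ė + α ((d⊤Ω̃)r)² ],   c = d⊤k_PC,

via the identity `c·r_PC = -ė + (d⊤Ω̃)r` (verified numerically at
arbitrary states, and the whole closed form against centered finite
differences of L along simulated runs; agreement within 1% of signal
scale away from saccade-pulse edges, ~1e-13 between pulses). The
certified boundary is `α ≤ (1-μ)·c`.

Two modeling notes. First, the heterosynaptic update `dΩ/dt` is applied
to the full matrix, including the diagonal, because the derivative
identity above requires the rule verbatim; a zero-diagonal projection
would be more literal biologically but breaks the exact identity, so it
is not used. Second, eye position is identified with the internal
representation `Ê` for slip computation — slip is computed directly
from the state equation rather than by differentiating a separately
integrated position.

## Synthetic inputs

Commands are constant/step/sinusoid signals; saccade trains are
non-overlapping rectangular velocity pulses with exponential
inter-saccade intervals (default mean 20 time units), seeded amplitudes
uniform in [-1, 1] interpreted as integrated displacement (pulse height
= amplitude / width, default width 0.1), giving unit-scale eye
positions and persistent activity throughout learning. The exact
running integral `E(t)` is available in closed form. Perturbations
come in additive (sinusoid, held uniform noise), signal-dependent
(`μ·e·sin(ωt)`, `μ·e·u(t)` with `u ∈ [-1,1]`), probe, and worst-case
(`ξ = -μe`, the sign that maximizes dL/dt) flavors; signal-dependent
realizations satisfy `|ξ| ≤ μ|e|` identically, sample by sample. All
generators are pure functions of (parameters, seed, t) — reruns are
bit-identical.

What the generator does *not* emulate: spiking climbing-fiber error
channels (errors are smooth rates), physiological retinal-slip
transduction, correlated or heavy-tailed noise, and saccade sequences
with realistic main-sequence statistics. Passing tests therefore
witness the dynamical claims — certificate validity, boundary
locations, resonance structure — under idealized drive, not robustness
to biological signal statistics.

## Numerical choices

- **Integration**: fixed-step classical RK4 everywhere, for exact
  reproducibility. Toy step: `min(0.01/η₁, 0.01·2π/ω_fastest)` where
  `ω_fastest` covers ωₙ and any input/perturbation frequency.
  Integrator step: 0.02 nondimensional units (the rate dynamics have
  unit time constant; 0.02 resolves them comfortably and keeps the
  fast–slow co-integration single-scheme). Oscillator step: 1/200 of
  the shorter of the forcing and natural periods.
- **Divergence guard**: integration halts and flags (never raises) when
  a gain exceeds `1e6·max(1, |w*|)` (toy) or any rate exceeds 1e6
  (integrator). The guard separates unbounded growth from large
  transients.
- **Semidefiniteness bisection**: the worst-case bracket is tested for
  positive semidefiniteness by an eigenvalue check plus a redundant
  720-point unit-circle direction scan (robust at the degenerate
  boundary where an eigenvalue touches zero, slack 1e-12); the critical
  parameter is bisected to 1e-8 by default (1e-6 in the acceptance
  script), doubling the upper bracket as needed.
- **Steady-state extraction**: least-squares fit of `a·sin + b·cos`
  over the final 5 forcing periods after discarding ten damping time
  constants `10/(ζωₙ)`; phase reported on the lag convention
  `x = -A sin(ωt - φ)`, matching the closed form's `[0, π)` branch.
- **Certification**: centered finite differences of L at every interior
  recorded sample; certified iff the maximum does not exceed the given
  tolerance (1e-8 in the certificate tests — comfortably above the
  O(h²) differencing error of stable runs, far below genuine
  violations, which are O(η₁·L)).
- **Classification**: converged requires terminal errors below 1e-3
  *and* a non-increasing error envelope over the trailing 10% window;
  divergent requires the guard or a terminal norm above 1e3; everything
  else is bounded-oscillatory, with the dominant period estimated from
  zero crossings (two per period) of the detrended consolidation error
  (toy) or cerebellar loop gain (integrator).
- **Circuit construction** (integrator): `d` is a seeded random unit
  vector; `k_PC = c·d + √(1-c²)·g` with `g` a unit vector orthogonal to
  `d`; `k_sacc` is a random direction rescaled so `d⊤k_sacc = 1`
  exactly. The initial `Ω` is `λ₀·dd⊤` plus per-column corrections
  `-λ₀ d_j²/(1-d_j²)·(e_j - d_j d)` that zero the diagonal while
  keeping `d` an exact left eigenvector — the detuning then sits in the
  readout direction, so `λ₀ = 1.05` is an unstable integrator whose
  drift is behaviorally visible.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| η₁ (toy) | 0.1 | 1/(time·rate²) | error-correction time constant ≈ 10 units at unit command |
| α = η₂/η₁ | 0.5 (stable demos) | — | mid-certificate; sweeps cover 0.05–25 |
| w* | 1 | — | unit target gain |
| μ | 0 unless stated | — | perturbation fraction; certificates exercised at 0.2–1.0 |
| η₁, η₂ (integrator) | 5e-3, 5e-4 | 1/time (nondim.) | learning ≪ rate dynamics (fast–slow separation ≥ 200×); interchange for the unstable regime |
| λ₀ | 1.05 | — | 20-time-constant drift, a clearly misbehaving integrator |
| c = d⊤k_PC | 0.9 | — | realistic imperfect alignment, still near the scalar-circuit limit |
| N | 20 | neurons | large enough for generic random geometry, small enough for second-scale runs |
| consolidation duration | 5000 | nondim. time | ≈ 2.5 late-stage time constants past the wPC peak; endpoint thresholds met with margin |

## Design choices on open points

- **Worst-case perturbation sign**: the certificate's binding
  realization is `ξ = -μe` (it makes the cross term `-η₁W̃ rin ξ`
  positive); this is what `WorstCasePerturbation` implements and what
  the certificate tests drive.
- **Toy instability drive**: a signal-dependent sinusoid modulates the
  effective early-stage rate as `(1 + μ sin ω_p t)` — a parametric
  (Mathieu-type) modulation. The principal parametric band `ω_p = 2ωₙ`
  is what destabilizes the α ≫ 1 regime in practice (product terms
  `μ e sin(ω_p t)` with `e` oscillating near ωₙ force at `ω_p - ωₙ =
  ωₙ`); the instability experiments use it. Quantitative Mathieu
  stability charts are out of scope — parametric resonance is used as
  mechanism, not as a fitted model.
- **Interchanged-rate regime**: with slow-early/fast-late rates and no
  perturbation the loop oscillates in weight space but eventually
  re-converges (the certificate is sufficient, not necessary). The
  `interchanged` experiment adds a signal-dependent sinusoid at the
  full envelope (μ = 1) tuned to the observed weight-space oscillation
  frequency (≈ 0.0066 rad/unit for the defaults), which sustains the
  alternation between unstable (λ_max ≈ 1.05–1.4) and leaky (≈ 0.93)
  tunings; the measured period (≈ 350 units) is reported as a
  diagnostic, not asserted against any external value.

## Known limitations

- Linear rate networks and a single lumped Purkinje population only;
  no spiking, no nonlinear transfer, no tuning of non-integrating
  modes.
- Full consolidation (`w_PC → 0`) requires the rate trajectory to
  excite the directions carrying the recurrent detuning. With a single
  saccadic input vector, small networks (N ≈ 5) plateau with a small
  compensating `w_PC` (~2e-3 for a 0.05 detuning) while the readout
  behaves perfectly; at N = 20 with the default drive the endpoint
  thresholds (‖w_PC‖ < 1e-3, |λ_max - 1| < 1e-3) are met. This is a
  persistent-excitation effect, not a solver artifact.
- The stability certificates are one-sided: above the boundary the
  package reports empirical labels (converge / oscillate / diverge) but
  asserts nothing, since instability is possible, not guaranteed.
- Finite-difference certification degrades at saccade-pulse edges where
  the rate derivative jumps; certificate checks either record densely
  (stride ≤ 0.1 time units) or mask stencil-straddling samples.
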