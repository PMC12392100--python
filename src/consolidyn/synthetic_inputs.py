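"""Seeded generators for command signals, saccade trains and perturbations.

Every input the simulations consume is produced here: the command signal
``rin(t)`` tracked by the gain-tuning circuit, velocity-pulse saccade
trains driving the neural integrator, and perturbation processes
corrupting the teaching signal.  Signal-dependent perturbations respect
the bound ``|xi(t)| <= mu * |e(t)|`` pointwise by construction, so the
stability certificates can be exercised at the edge of their assumptions.

All generators are pure functions of (parameters, seed, t): re-evaluating
with the same arguments is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InputSignal",
    "SaccadeTrain",
    "PerturbationModel",
    "make_input_signal",
    "make_saccade_train",
    "make_perturbation",
]

_INPUT_KINDS = ("constant", "step", "sinusoid")
_PERTURBATION_KINDS = (
    "none",
    "additive_sine",
    "additive_noise",
    "signal_dependent_sine",
    "signal_dependent_noise",
    "probe_sine",
)


@dataclass(frozen=True)
class InputSignal:
    """Time-varying command signal ``rin(t)``.

    Parameters
    ----------
    kind
        One of ``constant``, ``step`` or ``sinusoid``.
    amplitude
        Signal amplitude (rate units).
    onset
        Step onset time; the signal is 0 before and ``amplitude`` after.
        Ignored by the other kinds.
    frequency
        Angular frequency (rad / time) of the sinusoid.
    """

    kind: str
    amplitude: float = 1.0
    onset: float = 0.0
    frequency: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in _INPUT_KINDS:
            raise ValueError(f"unknown input kind {self.kind!r}")

    def __call__(self, t):
        if self.kind == "constant":
            return self.amplitude * np.ones_like(np.asarray(t, dtype=float))[()]
        if self.kind == "step":
            return np.where(np.asarray(t, dtype=float) >= self.onset, self.amplitude, 0.0)[()]
        return self.amplitude * np.sin(self.frequency * np.asarray(t, dtype=float))[()]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "onset": self.onset,
            "frequency": self.frequency,
        }


def make_input_signal(kind: str, **params) -> InputSignal:
    """Construct an :class:`InputSignal` of the given kind."""
    return InputSignal(kind=kind, **params)


@dataclass(frozen=True)
class SaccadeTrain:
    """Train of rectangular velocity pulses and its running integral.

    Each saccade is a rectangular velocity pulse of width ``pulse_width``
    whose time-integral equals the saccade amplitude (the displacement of
    the eye), so the pulse height is ``amplitude / pulse_width``.  Pulses
    must not overlap (sorted onset times at least ``pulse_width`` apart);
    the integrated eye position ``E(t)`` is then available in closed form.
    """

    times: np.ndarray
    amplitudes: np.ndarray
    pulse_width: float
    duration: float
    seed: int | None = None
    _cum: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size and np.any(np.diff(times) < self.pulse_width):
            raise ValueError("saccade pulses must be sorted and non-overlapping")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "_cum", np.concatenate([[0.0], np.cumsum(self.amplitudes)]))

    def velocity(self, t):
        """Velocity command ``Isacc(t)``."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.zeros(np.broadcast(t).shape)[()]
        idx = np.searchsorted(self.times, t, side="right")
        started = idx > 0
        k = np.maximum(idx - 1, 0)
        active = started & (t < self.times[k] + self.pulse_width)
        out = np.where(active, self.amplitudes[k] / self.pulse_width, 0.0)
        return out[()]

    def position(self, t):
        """Running integral ``E(t) = ∫₀ᵗ Isacc ds`` (exact)."""
        t = np.asarray(t, dtype=float)
        if self.times.size == 0:
            return np.zeros(np.broadcast(t).shape)[()]
        idx = np.searchsorted(self.times, t, side="right")
        k = np.maximum(idx - 1, 0)
        frac = np.clip((t - self.times[k]) / self.pulse_width, 0.0, 1.0)
        out = np.where(idx > 0, self._cum[k] + self.amplitudes[k] * frac, 0.0)
        return out[()]

    __call__ = velocity

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "amplitudes": self.amplitudes.tolist(),
            "pulse_width": self.pulse_width,
            "duration": self.duration,
            "seed": self.seed,
        }


def make_saccade_train(
    mean_interval: float = 20.0,
    amplitude_range: tuple[float, float] = (-1.0, 1.0),
    pulse_width: float = 0.1,
    duration: float = 1000.0,
    seed: int = 0,
) -> SaccadeTrain:
    """Sample a saccade train with exponential inter-saccade intervals.

    ``mean_interval = inf`` yields an empty train (``Isacc ≡ 0``).
    Identical arguments (including the seed) give identical trains.
    """
    if pulse_width <= 0 or duration <= 0:
        raise ValueError("pulse_width and duration must be positive")
    if not math.isfinite(mean_interval):
        return SaccadeTrain(
            times=np.empty(0),
            amplitudes=np.empty(0),
            pulse_width=pulse_width,
            duration=duration,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    times = []
    t = rng.exponential(mean_interval)
    while t < duration - pulse_width:
        times.append(t)
        t += pulse_width + rng.exponential(mean_interval)
    times = np.asarray(times)
    amplitudes = rng.uniform(amplitude_range[0], amplitude_range[1], size=times.size)
    return SaccadeTrain(
        times=times,
        amplitudes=amplitudes,
        pulse_width=pulse_width,
        duration=duration,
        seed=seed,
    )


@dataclass(frozen=True)
class PerturbationModel:
    """Specification of a perturbation process ``xi(t; e)``.

    Kinds
    -----
    none
        ``xi ≡ 0``.
    additive_sine
        ``A·sin(ω t)``; independent of the error.
    additive_noise
        Seeded piecewise-constant uniform noise in ``[-A, A]``.
    signal_dependent_sine
        ``mu · e · sin(ω t)``; satisfies ``|xi| <= mu |e|`` exactly.
    signal_dependent_noise
        ``mu · e · u(t)`` with seeded ``u(t) ∈ [-1, 1]``.
    probe_sine
        ``ε · sin(ω t)``, the infinitesimal probe used in the resonance
        analysis.
    """

    kind: str = "none"
    amplitude: float = 0.0  # A for additive kinds, epsilon for the probe
    mu: float = 0.0
    frequency: float = 1.0
    seed: int = 0
    noise_dt: float = 0.5  # hold time of the piecewise-constant noise

    def __post_init__(self) -> None:
        if self.kind not in _PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "amplitude": self.amplitude,
            "mu": self.mu,
            "frequency": self.frequency,
            "seed": self.seed,
            "noise_dt": self.noise_dt,
        }


class _HeldNoise:
    """Deterministic piecewise-constant uniform noise in [-1, 1].

    The value on bin ``k`` is a pure function of (seed, k), so evaluation
    order does not matter and reruns are bit-identical.
    """

    def __init__(self, seed: int, dt: float):
        self.seed = int(seed)
        self.dt = float(dt)
        self._cache: dict[int, float] = {}

    def __call__(self, t: float) -> float:
        k = int(math.floor(t / self.dt))
        v = self._cache.get(k)
        if v is None:
            v = float(np.random.default_rng([self.seed, k & 0x7FFFFFFF, k < 0]).uniform(-1.0, 1.0))
            self._cache[k] = v
        return v


@dataclass
class Perturbation:
    """Evaluable perturbation ``xi(t, e)`` realizing a :class:`PerturbationModel`."""

    model: PerturbationModel
    _noise: _HeldNoise | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.model.kind in ("additive_noise", "signal_dependent_noise"):
            self._noise = _HeldNoise(self.model.seed, self.model.noise_dt)

    @property
    def signal_dependent(self) -> bool:
        return self.model.kind.startswith("signal_dependent")

    def __call__(self, t: float, e: float = 0.0) -> float:
        m = self.model
        if m.kind == "none":
            return 0.0
        if m.kind == "additive_sine":
            return m.amplitude * math.sin(m.frequency * t)
        if m.kind == "additive_noise":
            return m.amplitude * self._noise(t)
        if m.kind == "signal_dependent_sine":
            return m.mu * e * math.sin(m.frequency * t)
        if m.kind == "signal_dependent_noise":
            return m.mu * e * self._noise(t)
        # probe_sine
        return m.amplitude * math.sin(m.frequency * t)


def make_perturbation(model: PerturbationModel | None) -> Perturbation:
    """Realize a perturbation model as an evaluable ``xi(t, e)``."""
    if model is None:
        model = PerturbationModel(kind="none")
    return Perturbation(model)
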