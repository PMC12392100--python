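"""Two-stage gain-tracking circuit and its numerical integration.

The circuit learns to map a command signal ``rin(t)`` to a desired output
``w* · rin(t)`` through two parallel pathways: an early, indirect pathway
with gain ``w1`` trained directly by the (possibly perturbed) tracking
error, and a late, direct pathway with gain ``w2`` trained only by the
early stage's corrective output ``r1 = w1 · rin``.  Learning rules::

    dw1/dt = -eta1 * rin * (e + xi)        (delta rule, early stage)
    dw2/dt =  eta2 * rin * (w1 * rin)      (heterosynaptic rule, late stage)

with tracking error ``e = (w1 + w2 - w*) * rin`` and perturbation
``xi(t)`` bounded by ``|xi| <= mu |e|`` in the signal-dependent regime.
Successful consolidation drives the gain error ``W~ = w1 + w2 - w*`` and
the consolidation error ``w~2 = w2 - w*`` to zero, leaving the memory
stored entirely in the late stage (``w1 = 0``, ``w2 = w*``).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_inputs import (
    InputSignal,
    Perturbation,
    PerturbationModel,
    make_perturbation,
)

__all__ = [
    "ToyParams",
    "ToyState",
    "Trajectory",
    "SolverConfig",
    "ClassifyThresholds",
    "Classification",
    "toy_output_and_error",
    "toy_rhs",
    "simulate_toy",
    "classify_trajectory",
]

_MODES = ("single_stage", "two_stage")


@dataclass(frozen=True)
class ToyParams:
    """Parameters of the two-stage gain-tracking circuit.

    Attributes
    ----------
    w_star
        Desired input-to-output gain (dimensionless).
    eta1
        Early-stage learning rate (1 / time per squared rate unit).
    eta2
        Late-stage (consolidation) learning rate, same units.
    mu
        Signal-dependent perturbation fraction; the teaching signal may
        be corrupted by any ``xi`` with ``|xi| <= mu |e|``.
    """

    w_star: float = 1.0
    eta1: float = 0.1
    eta2: float = 0.05
    mu: float = 0.0

    def __post_init__(self) -> None:
        if self.eta1 <= 0:
            raise ValueError("eta1 must be positive")
        if self.eta2 < 0:
            raise ValueError("eta2 must be non-negative")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    @property
    def alpha(self) -> float:
        """Learning-rate ratio ``alpha = eta2 / eta1``."""
        return self.eta2 / self.eta1

    def to_dict(self) -> dict:
        return {
            "w_star": self.w_star,
            "eta1": self.eta1,
            "eta2": self.eta2,
            "mu": self.mu,
        }


@dataclass
class ToyState:
    """Instantaneous state of the circuit: time and the two gains."""

    t: float = 0.0
    w1: float = 0.0
    w2: float = 0.0

    def gain_error(self, w_star: float) -> float:
        """``W~ = w1 + w2 - w*``."""
        return self.w1 + self.w2 - w_star

    def consolidation_error(self, w_star: float) -> float:
        """``w~2 = w2 - w*``."""
        return self.w2 - w_star


def toy_output_and_error(state: ToyState, rin_value: float, w_star: float):
    """Circuit output and tracking error at one instant.

    Returns ``(ro, e)`` with ``ro = (w1 + w2) rin`` and
    ``e = (w1 + w2 - w*) rin``.
    """
    ro = (state.w1 + state.w2) * rin_value
    e = (state.w1 + state.w2 - w_star) * rin_value
    return ro, e


def toy_rhs(
    state: ToyState,
    rin_value: float,
    xi_value: float,
    params: ToyParams,
    mode: str = "two_stage",
):
    """Right-hand side of the learning ODEs.

    In ``single_stage`` mode the late stage is frozen (``dw2/dt = 0``).
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {_MODES}")
    _, e = toy_output_and_error(state, rin_value, params.w_star)
    dw1 = -params.eta1 * rin_value * (e + xi_value)
    if mode == "single_stage":
        dw2 = 0.0
    else:
        dw2 = params.eta2 * rin_value * (state.w1 * rin_value)
    return dw1, dw2


@dataclass(frozen=True)
class SolverConfig:
    """Fixed-step RK4 configuration.

    ``step=None`` auto-selects ``min(0.01/eta1, 0.01·2π/ω_fastest)`` where
    ``ω_fastest`` is the largest of the natural frequency
    ``ω_n = sqrt(eta1·eta2)`` and any input / perturbation frequency.
    """

    step: float | None = None
    record_stride: int = 1
    divergence_bound: float | None = None  # default 1e6 * max(1, |w*|)

    def resolve_step(self, params: ToyParams, frequencies: list[float]) -> float:
        if self.step is not None:
            return self.step
        h = 0.01 / params.eta1
        omega_fastest = max(
            [math.sqrt(params.eta1 * params.eta2)] + [abs(f) for f in frequencies if f]
            or [0.0]
        )
        if omega_fastest > 0:
            h = min(h, 0.01 * 2 * math.pi / omega_fastest)
        return h


@dataclass
class Trajectory:
    """Sampled trajectory of a gain-tracking simulation.

    Arrays all share one uniform time grid.  ``xi`` holds the realized
    perturbation at each sample; for signal-dependent perturbations the
    stored samples satisfy ``|xi| <= mu |e|`` exactly.
    """

    t: np.ndarray
    w1: np.ndarray
    w2: np.ndarray
    ro: np.ndarray
    e: np.ndarray
    xi: np.ndarray
    rin: np.ndarray
    params: ToyParams
    mode: str = "two_stage"
    divergent: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("w1", "w2", "ro", "e", "xi", "rin"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} length mismatch")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def gain_error(self) -> np.ndarray:
        return self.w1 + self.w2 - self.params.w_star

    @property
    def consolidation_error(self) -> np.ndarray:
        return self.w2 - self.params.w_star

    @property
    def step(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else math.nan

    def to_frame(self, lyapunov_b: float | None = 1.0) -> pd.DataFrame:
        """Tabulate the trajectory; optionally append L and its finite
        difference for the weighting ``b`` of the consolidation error."""
        df = pd.DataFrame(
            {
                "t": self.t,
                "w1": self.w1,
                "w2": self.w2,
                "ro": self.ro,
                "e": self.e,
                "xi": self.xi,
            }
        )
        if lyapunov_b is not None and len(self.t) > 2:
            W = self.gain_error
            w2t = self.consolidation_error
            L = 0.5 * (W**2 + lyapunov_b * w2t**2)
            df["L"] = L
            df["dLdt"] = np.gradient(L, self.t)
        return df

    def to_csv(self, path: str | Path, **meta) -> None:
        """Write the trajectory as CSV with a JSON metadata sidecar."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "params": self.params.to_dict(),
            "mode": self.mode,
            "divergent": self.divergent,
            **self.meta,
            **meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def simulate_toy(
    params: ToyParams,
    input_signal: InputSignal,
    perturbation: Perturbation | PerturbationModel | None = None,
    mode: str = "two_stage",
    initial: ToyState | None = None,
    duration: float = 500.0,
    solver: SolverConfig | None = None,
) -> Trajectory:
    """Integrate the learning ODEs with a fixed-step classical RK4 scheme.

    The perturbation is evaluated inside the right-hand side as
    ``xi(t, e(t))`` so signal-dependent realizations track the concurrent
    error.  If either gain exceeds the divergence bound, integration
    halts and the trajectory is flagged ``divergent`` (no exception).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if perturbation is None or isinstance(perturbation, PerturbationModel):
        perturbation = make_perturbation(perturbation)
    if initial is None:
        initial = ToyState()
    solver = solver or SolverConfig()
    freqs = [getattr(input_signal, "frequency", 0.0) if input_signal.kind == "sinusoid" else 0.0,
             perturbation.model.frequency if perturbation.model.kind != "none" else 0.0]
    h = solver.resolve_step(params, freqs)
    bound = solver.divergence_bound
    if bound is None:
        bound = 1e6 * max(1.0, abs(params.w_star))

    n_steps = int(math.ceil(duration / h))
    eta1, eta2, w_star = params.eta1, params.eta2, params.w_star
    two_stage = mode == "two_stage"
    rin_f = input_signal
    xi_f = perturbation

    def deriv(t, w1, w2):
        rin = float(rin_f(t))
        e = (w1 + w2 - w_star) * rin
        xi = xi_f(t, e)
        dw1 = -eta1 * rin * (e + xi)
        dw2 = eta2 * rin * (w1 * rin) if two_stage else 0.0
        return dw1, dw2

    stride = max(1, int(solver.record_stride))
    ts, w1s, w2s = [], [], []
    t, w1, w2 = initial.t, initial.w1, initial.w2
    divergent = False
    for i in range(n_steps + 1):
        if i % stride == 0 or i == n_steps:
            ts.append(t)
            w1s.append(w1)
            w2s.append(w2)
        if i == n_steps:
            break
        k1 = deriv(t, w1, w2)
        k2 = deriv(t + h / 2, w1 + h / 2 * k1[0], w2 + h / 2 * k1[1])
        k3 = deriv(t + h / 2, w1 + h / 2 * k2[0], w2 + h / 2 * k2[1])
        k4 = deriv(t + h, w1 + h * k3[0], w2 + h * k3[1])
        w1 += h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        w2 += h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        t = initial.t + (i + 1) * h
        if not (math.isfinite(w1) and math.isfinite(w2)) or abs(w1) > bound or abs(w2) > bound:
            divergent = True
            ts.append(t)
            w1s.append(w1 if math.isfinite(w1) else math.copysign(bound, w1))
            w2s.append(w2 if math.isfinite(w2) else math.copysign(bound, w2))
            break

    t_arr = np.asarray(ts)
    w1_arr = np.asarray(w1s)
    w2_arr = np.asarray(w2s)
    rin_arr = np.asarray([float(rin_f(tv)) for tv in t_arr])
    e_arr = (w1_arr + w2_arr - w_star) * rin_arr
    ro_arr = (w1_arr + w2_arr) * rin_arr
    xi_arr = np.asarray([xi_f(tv, ev) for tv, ev in zip(t_arr, e_arr)])
    return Trajectory(
        t=t_arr,
        w1=w1_arr,
        w2=w2_arr,
        ro=ro_arr,
        e=e_arr,
        xi=xi_arr,
        rin=rin_arr,
        params=params,
        mode=mode,
        divergent=divergent,
        meta={
            "step": h,
            "duration": duration,
            "perturbation": perturbation.model.to_dict(),
            "input": input_signal.to_dict(),
        },
    )


@dataclass(frozen=True)
class ClassifyThresholds:
    """Thresholds for trajectory classification.

    ``tol``: residual below which terminal errors count as converged.
    ``bound``: terminal norm above which the run counts as divergent
    even if the integration guard never tripped.
    ``window_fraction``: trailing fraction of samples over which the
    error envelope must be non-increasing for convergence.
    """

    tol: float = 1e-3
    bound: float = 1e3
    window_fraction: float = 0.1


@dataclass(frozen=True)
class Classification:
    label: str  # converged | bounded_oscillatory | divergent
    residual: float
    period: float | None = None


def classify_trajectory(
    traj: Trajectory, thresholds: ClassifyThresholds | None = None
) -> Classification:
    """Label a trajectory as converged, bounded_oscillatory or divergent.

    Converged requires both terminal errors (|W~|, |w~2|) below ``tol``
    and a non-increasing error envelope over the trailing window.
    Divergent means the integration guard tripped or the terminal norm
    exceeds ``bound``.  Otherwise the run is bounded_oscillatory, with a
    dominant period estimated from zero-crossings of the consolidation
    error about its trailing mean.
    """
    if len(traj.t) == 0:
        raise ValueError("cannot classify an empty trajectory")
    th = thresholds or ClassifyThresholds()
    W = traj.gain_error
    w2t = traj.consolidation_error
    norm = np.hypot(W, w2t)
    residual = float(norm[-1])
    if traj.divergent or residual > th.bound:
        return Classification(label="divergent", residual=residual)
    n_win = max(2, int(len(norm) * th.window_fraction))
    tail = norm[-n_win:]
    # envelope check on coarse halves to be robust to ripple
    non_increasing = tail[: n_win // 2].max() >= tail[n_win // 2 :].max() - th.tol
    if abs(W[-1]) < th.tol and abs(w2t[-1]) < th.tol and non_increasing:
        return Classification(label="converged", residual=residual)
    x = w2t - w2t[len(w2t) // 2 :].mean()
    sign = np.sign(x)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    period = None
    if len(crossings) >= 3:
        # two crossings per period
        span = traj.t[crossings[-1]] - traj.t[crossings[0]]
        period = float(2 * span / (len(crossings) - 1))
    return Classification(label="bounded_oscillatory", residual=residual, period=period)
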