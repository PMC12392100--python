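"""Cerebellar tuning and consolidation of a linear neural integrator.

An N-neuron linear recurrent network integrates velocity-encoding
saccadic commands into a persistent eye-position signal read out as
``Ê = d⊤r``.  Perfect integration requires the recurrent matrix ``Ω`` to
hold a unity eigenvalue along the readout direction; detuned networks
drift (leaky) or run away (unstable).  A lumped cerebellar Purkinje-cell
pathway closes a loop around the network: fast plasticity of the
Purkinje input weights ``wPC`` is driven by the retinal-slip rate ``ė``
(a delta rule), while the recurrent weights consolidate slowly from the
Purkinje rate ``rPC = wPC⊤r`` (a heterosynaptic rule).  In
nondimensional units (time and rates in units of the neuronal time
constant)::

    dr/dt   = -r + Ω r - kPC (wPC⊤ r) + ksacc · Isacc
    dwPC/dt = eta1 · (ė + ξ) · r
    dΩ/dt   = -eta2 · kPC · rPC · r⊤

with slip rate ``ė = -(d⊤W~) r`` where ``W~ = kPC wPC⊤ + I - Ω`` (the
saccadic pathway is calibrated so ``d⊤ksacc = 1``).  The Lyapunov
candidate ``L = ½‖d⊤W~‖² + ½‖d⊤Ω~‖²`` (with ``d⊤Ω~ = d⊤Ω - d⊤``)
decreases along trajectories whenever ``α = eta2/eta1 ≤ (1-mu)·c`` where
``c = d⊤kPC`` is the alignment (cosine) between the readout and the
cerebellar projection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .lyapunov import StabilityVerdict, bisect_semidefinite
from .synthetic_inputs import Perturbation, PerturbationModel, SaccadeTrain, make_perturbation
from .toy_model import Classification

__all__ = [
    "IntegratorSystem",
    "IntegratorState",
    "NISolverConfig",
    "NITrajectory",
    "IntegratorDiagnostics",
    "build_system",
    "network_rhs",
    "retinal_slip_rate",
    "learning_rhs",
    "lyapunov_NI",
    "ldot_NI_analytic",
    "critical_alpha_NI",
    "simulate_consolidation",
    "classify_consolidation",
    "inactivation_probe",
    "integrator_diagnostics",
]


@dataclass(frozen=True)
class IntegratorSystem:
    """Fixed circuit structure and learning hyperparameters.

    ``d`` is the unit-norm eye-position decoder, ``kPC`` the unit-norm
    cerebellar projection (so ``c = d⊤kPC`` is a cosine), and ``ksacc``
    the saccadic input vector calibrated to ``d⊤ksacc = 1``.  ``tau`` is
    the neuronal time constant used only when re-dimensionalizing
    reported quantities.
    """

    N: int
    d: np.ndarray
    kPC: np.ndarray
    ksacc: np.ndarray
    eta1: float = 5e-3
    eta2: float = 5e-4
    mu: float = 0.0
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.eta1 <= 0:
            raise ValueError("eta1 must be positive")
        if self.c_align <= 0:
            raise ValueError("alignment d.kPC must be positive")

    @property
    def c_align(self) -> float:
        """Alignment scalar ``c = d⊤kPC`` (cosine for unit vectors)."""
        return float(self.d @ self.kPC)

    @property
    def alpha(self) -> float:
        return self.eta2 / self.eta1

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "d": self.d.tolist(),
            "kPC": self.kPC.tolist(),
            "ksacc": self.ksacc.tolist(),
            "eta1": self.eta1,
            "eta2": self.eta2,
            "mu": self.mu,
            "tau": self.tau,
        }


@dataclass
class IntegratorState:
    """Dynamical state: rates, Purkinje weights and recurrent matrix."""

    t: float
    r: np.ndarray
    wPC: np.ndarray
    Omega: np.ndarray

    def rPC(self) -> float:
        """Purkinje-cell rate ``wPC⊤r``."""
        return float(self.wPC @ self.r)

    def Ehat(self, system: IntegratorSystem) -> float:
        """Internal eye-position estimate ``d⊤r``."""
        return float(system.d @ self.r)

    def readout_gain_error(self, system: IntegratorSystem) -> np.ndarray:
        """Row vector ``d⊤W~ = c·wPC⊤ + d⊤ - d⊤Ω`` (as a 1-D array)."""
        return system.c_align * self.wPC + system.d - self.Omega.T @ system.d

    def readout_detuning(self, system: IntegratorSystem) -> np.ndarray:
        """Row vector ``d⊤Ω~ = d⊤Ω - d⊤``.

        Any desired matrix ``Ω*`` with ``d⊤Ω* = d⊤`` gives this same
        readout projection, so no explicit choice of ``Ω*`` is needed.
        """
        return self.Omega.T @ system.d - system.d

    def copy(self) -> "IntegratorState":
        return IntegratorState(self.t, self.r.copy(), self.wPC.copy(), self.Omega.copy())


def build_system(
    N: int = 20,
    c_align_target: float = 0.9,
    lambda0: float = 1.05,
    seed: int = 0,
    eta1: float = 5e-3,
    eta2: float = 5e-4,
    mu: float = 0.0,
    tau: float = 1.0,
) -> tuple[IntegratorSystem, IntegratorState]:
    """Construct a detuned integrator circuit and its initial state.

    ``d`` is a seeded random unit vector; ``kPC`` is a unit vector at
    cosine ``c_align_target`` to ``d``; ``ksacc`` is scaled so that
    ``d⊤ksacc = 1`` exactly.  The initial recurrent matrix has zero
    diagonal and leading eigenvalue ``lambda0`` with left eigenvector
    ``d``, so the detuning is visible in the readout: ``lambda0 > 1``
    yields an unstable integrator, ``< 1`` a leaky one.  Purkinje
    weights start at zero.
    """
    if N < 2:
        raise ValueError("need at least two neurons")
    if not 0 < c_align_target <= 1:
        raise ValueError("alignment cosine must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    d = rng.standard_normal(N)
    d /= np.linalg.norm(d)

    g = rng.standard_normal(N)
    g -= (d @ g) * d
    g /= np.linalg.norm(g)
    kPC = c_align_target * d + math.sqrt(max(0.0, 1.0 - c_align_target**2)) * g

    s = rng.standard_normal(N)
    while abs(d @ s) < 0.1:
        s = rng.standard_normal(N)
    ksacc = s / (d @ s)

    # Omega = lambda0·d d⊤ plus per-column corrections that zero the
    # diagonal while keeping d an exact left eigenvector
    Omega = lambda0 * np.outer(d, d)
    for j in range(N):
        dj2 = d[j] ** 2
        if dj2 >= 1.0 - 1e-12:
            raise ValueError("decoder too concentrated on one neuron")
        ej = np.zeros(N)
        ej[j] = 1.0
        Omega[:, j] += (-lambda0 * dj2 / (1.0 - dj2)) * (ej - d[j] * d)
    lam = np.linalg.eigvals(Omega)
    if abs(lam.real.max() - lambda0) > 1e-8:
        raise ValueError("construction failed to place the leading eigenvalue")

    system = IntegratorSystem(N=N, d=d, kPC=kPC, ksacc=ksacc, eta1=eta1, eta2=eta2, mu=mu, tau=tau)
    state = IntegratorState(t=0.0, r=np.zeros(N), wPC=np.zeros(N), Omega=Omega)
    return system, state


def network_rhs(state: IntegratorState, Isacc_value: float, system: IntegratorSystem) -> np.ndarray:
    """Rate dynamics ``dr/dt = -r + Ωr - kPC(wPC⊤r) + ksacc·Isacc``."""
    return (
        -state.r
        + state.Omega @ state.r
        - system.kPC * (state.wPC @ state.r)
        + system.ksacc * Isacc_value
    )


def retinal_slip_rate(state: IntegratorState, Isacc_value: float, system: IntegratorSystem) -> float:
    """Slip rate ``ė = -(d⊤W~)r + (d⊤ksacc - 1)·Isacc``.

    With the calibration ``d⊤ksacc = 1`` the command term vanishes and
    the slip is driven purely by the readout-projected tuning error.
    """
    cmd = float(system.d @ system.ksacc) - 1.0
    return float(-(state.readout_gain_error(system) @ state.r) + cmd * Isacc_value)


def learning_rhs(
    state: IntegratorState, edot: float, xi_value: float, system: IntegratorSystem
) -> tuple[np.ndarray, np.ndarray]:
    """Plasticity rules ``dwPC/dt = eta1(ė+ξ)r`` and
    ``dΩ/dt = -eta2·kPC·rPC·r⊤`` (rank one, columns along ``kPC``)."""
    dwPC = system.eta1 * (edot + xi_value) * state.r
    dOmega = (-system.eta2 * state.rPC()) * np.outer(system.kPC, state.r)
    return dwPC, dOmega


def lyapunov_NI(state: IntegratorState, system: IntegratorSystem) -> tuple[float, float, float]:
    """Lyapunov value ``L = ½‖d⊤W~‖² + ½‖d⊤Ω~‖²`` and its two terms."""
    u = state.readout_gain_error(system)
    v = state.readout_detuning(system)
    gain_term = 0.5 * float(u @ u)
    consolidation_term = 0.5 * float(v @ v)
    return gain_term + consolidation_term, gain_term, consolidation_term


def ldot_NI_analytic(
    state: IntegratorState, edot: float, xi_value: float, system: IntegratorSystem
) -> float:
    """Analytic ``dL/dt = -eta1[(c-α)ė² + c·ξ·ė + α((d⊤Ω~)r)²]``.

    Bounding ``|ξ| ≤ mu|ė|`` adversarially gives
    ``dL/dt ≤ -eta1[(c-α-c·mu)ė² + α((d⊤Ω~)r)²]``, non-positive whenever
    ``α ≤ (1-mu)c``.
    """
    c = system.c_align
    alpha = system.alpha
    q = float(state.readout_detuning(system) @ state.r)
    return -system.eta1 * ((c - alpha) * edot**2 + c * xi_value * edot + alpha * q**2)


def critical_alpha_NI(
    c_align: float, mu: float, method: str = "bisection_psd", tol: float = 1e-8
) -> StabilityVerdict:
    """Critical learning-rate ratio ``α_c = (1-mu)·c`` for the integrator.

    Obtained by bisection on the positive semidefiniteness of the
    worst-case bound expressed as a quadratic form in the scalar pair
    ``(ė, (d⊤Ω~)r)``; the closed form is ``max(0, (1-mu)c)``.
    """
    if c_align <= 0:
        raise ValueError("alignment c must be positive (stability analysis assumes c > 0)")
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if method == "closed_form":
        return StabilityVerdict(max(0.0, (1.0 - mu) * c_align), method, 0.0)
    if method != "bisection_psd":
        raise ValueError(f"unknown method {method!r}")

    def form(alpha: float) -> np.ndarray:
        return np.array([[c_align - alpha - c_align * mu, 0.0], [0.0, alpha]])

    alpha_c = bisect_semidefinite(form, tol=tol)
    return StabilityVerdict(alpha_c, method, tol)


@dataclass(frozen=True)
class NISolverConfig:
    """Fixed-step RK4 configuration for the fast–slow co-integration.

    The single step must resolve the (nondimensional, unit-time-constant)
    rate dynamics; the default 0.02 does so comfortably.  Diagnostics are
    recorded every ``record_stride`` steps; full ``(wPC, Ω)`` snapshots
    every ``snapshot_stride`` records (0 disables snapshots).
    """

    step: float = 0.02
    record_stride: int = 50
    snapshot_stride: int = 0
    divergence_bound: float = 1e6

    def __post_init__(self) -> None:
        if self.step > 0.2:
            raise ValueError("step too coarse for the unit-time-constant rate dynamics")


@dataclass
class NITrajectory:
    """Recorded diagnostics of a consolidation run."""

    t: np.ndarray
    Ehat: np.ndarray
    E: np.ndarray
    edot: np.ndarray
    xi: np.ndarray
    q_proj: np.ndarray
    L: np.ndarray
    wPC_norm: np.ndarray
    loop_gain: np.ndarray
    lambda_max: np.ndarray
    system: IntegratorSystem
    final_state: IntegratorState
    divergent: bool = False
    snapshots: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "E": self.E,
                "Ehat": self.Ehat,
                "edot": self.edot,
                "xi": self.xi,
                "q_proj": self.q_proj,
                "L": self.L,
                "wPC_norm": self.wPC_norm,
                "loop_gain": self.loop_gain,
                "lambda_max": self.lambda_max,
            }
        )

    def to_csv(self, path: str | Path, **meta) -> None:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "system": self.system.to_dict(),
            "divergent": self.divergent,
            **self.meta,
            **meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def simulate_consolidation(
    system: IntegratorSystem,
    initial: IntegratorState,
    saccades: SaccadeTrain,
    perturbation: Perturbation | PerturbationModel | None = None,
    duration: float = 5000.0,
    solver: NISolverConfig | None = None,
) -> NITrajectory:
    """Co-integrate rates and both plasticity rules with fixed-step RK4.

    The perturbation is evaluated as ``ξ(t, ė)`` so signal-dependent
    realizations track the concurrent slip rate.  If any state entry
    exceeds the divergence bound the run halts and is flagged divergent.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if perturbation is None or isinstance(perturbation, PerturbationModel):
        perturbation = make_perturbation(perturbation)
    solver = solver or NISolverConfig()
    h = solver.step
    n_steps = int(math.ceil(duration / h))
    d, kPC, ksacc = system.d, system.kPC, system.ksacc
    c, eta1, eta2 = system.c_align, system.eta1, system.eta2
    vel = saccades.velocity
    xi_f = perturbation
    bound = solver.divergence_bound

    r = initial.r.copy()
    wPC = initial.wPC.copy()
    Omega = initial.Omega.copy()
    t0 = initial.t

    def deriv(t, r, wPC, Omega):
        Isacc = float(vel(t))
        dW_row = c * wPC + d - Omega.T @ d  # d^T Wtilde
        edot = -float(dW_row @ r) + (float(d @ ksacc) - 1.0) * Isacc
        xi = xi_f(t, edot)
        rPC = float(wPC @ r)
        dr = -r + Omega @ r - kPC * rPC + ksacc * Isacc
        dwPC = eta1 * (edot + xi) * r
        dOmega = (-eta2 * rPC) * np.outer(kPC, r)
        return dr, dwPC, dOmega, edot, xi

    stride = max(1, int(solver.record_stride))
    rec_t, rec_Ehat, rec_edot, rec_xi, rec_L = [], [], [], [], []
    rec_q, rec_wnorm, rec_loop, rec_lmax = [], [], [], []
    snapshots = []
    divergent = False

    def record(t, r, wPC, Omega, edot, xi, idx):
        rec_t.append(t)
        rec_Ehat.append(float(d @ r))
        rec_edot.append(edot)
        rec_xi.append(xi)
        u = c * wPC + d - Omega.T @ d
        v = Omega.T @ d - d
        rec_q.append(float(v @ r))
        rec_L.append(0.5 * float(u @ u) + 0.5 * float(v @ v))
        rec_wnorm.append(float(np.linalg.norm(wPC)))
        rec_loop.append(float(wPC @ kPC))
        rec_lmax.append(float(np.linalg.eigvals(Omega).real.max()))
        if solver.snapshot_stride and idx % (stride * solver.snapshot_stride) == 0:
            snapshots.append((t, wPC.copy(), Omega.copy()))

    for i in range(n_steps + 1):
        t = t0 + i * h
        if i % stride == 0 or i == n_steps:
            k0 = deriv(t, r, wPC, Omega)
            record(t, r, wPC, Omega, k0[3], k0[4], i)
        if i == n_steps:
            break
        k1 = deriv(t, r, wPC, Omega)
        k2 = deriv(t + h / 2, r + h / 2 * k1[0], wPC + h / 2 * k1[1], Omega + h / 2 * k1[2])
        k3 = deriv(t + h / 2, r + h / 2 * k2[0], wPC + h / 2 * k2[1], Omega + h / 2 * k2[2])
        k4 = deriv(t + h, r + h * k3[0], wPC + h * k3[1], Omega + h * k3[2])
        r = r + h / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        wPC = wPC + h / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        Omega = Omega + h / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        if not np.isfinite(r).all() or np.abs(r).max() > bound:
            divergent = True
            break

    t_arr = np.asarray(rec_t)
    final = IntegratorState(t=t_arr[-1] if divergent else t0 + n_steps * h, r=r, wPC=wPC, Omega=Omega)
    return NITrajectory(
        t=t_arr,
        Ehat=np.asarray(rec_Ehat),
        E=np.asarray(saccades.position(t_arr), dtype=float),
        edot=np.asarray(rec_edot),
        xi=np.asarray(rec_xi),
        q_proj=np.asarray(rec_q),
        L=np.asarray(rec_L),
        wPC_norm=np.asarray(rec_wnorm),
        loop_gain=np.asarray(rec_loop),
        lambda_max=np.asarray(rec_lmax),
        system=system,
        final_state=final,
        divergent=divergent,
        snapshots=snapshots,
        meta={
            "step": h,
            "duration": duration,
            "perturbation": perturbation.model.to_dict(),
            "saccades": {"seed": saccades.seed, "n_pulses": int(saccades.times.size)},
        },
    )


def classify_consolidation(
    traj: NITrajectory, tol: float = 1e-3, window_fraction: float = 0.1
) -> Classification:
    """Label a consolidation run: converged, bounded_oscillatory or divergent.

    Converged requires a consolidated endpoint (``‖wPC‖`` below ``tol``
    and the recurrent matrix within ``tol`` of a unity leading
    eigenvalue) with non-increasing L over the trailing window.
    Otherwise the run is oscillatory, with the dominant weight-space
    period measured from zero crossings of the detrended loop gain.
    """
    if len(traj.t) == 0:
        raise ValueError("cannot classify an empty trajectory")
    if traj.divergent:
        return Classification(label="divergent", residual=float(traj.L[-1]))
    residual = float(traj.L[-1])
    n_win = max(2, int(len(traj.L) * window_fraction))
    tail = traj.L[-n_win:]
    non_increasing = tail[: n_win // 2].max() >= tail[n_win // 2 :].max() - tol
    if traj.wPC_norm[-1] < tol and abs(traj.lambda_max[-1] - 1.0) < tol and non_increasing:
        return Classification(label="converged", residual=residual)
    x = traj.loop_gain - traj.loop_gain.mean()
    crossings = np.nonzero(np.diff(np.sign(x)) != 0)[0]
    period = None
    if len(crossings) >= 3:
        period = float(2 * (traj.t[crossings[-1]] - traj.t[crossings[0]]) / (len(crossings) - 1))
    return Classification(label="bounded_oscillatory", residual=residual, period=period)


def inactivation_probe(
    state: IntegratorState,
    system: IntegratorSystem,
    horizon: float = 20.0,
    readout_value: float = 1.0,
) -> tuple[float, float, float]:
    """Fixation drift with and without the cerebellar pathway.

    From rates initialized along the decoder so that ``Ê(0)`` equals
    ``readout_value``, the network evolves freely (no saccades, learning
    frozen) for ``horizon`` time units, once with the Purkinje loop
    intact and once with ``wPC`` zeroed (in-silico inactivation).
    Returns ``(drift_with, drift_without, dependence_index)`` where each
    drift is ``|Ê(h) - Ê(0)| / |Ê(0)|`` and the dependence index is
    ``drift_without - drift_with``: near zero once the memory is
    consolidated into the recurrent weights, substantially positive
    while function still rests on the cerebellar loop.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if readout_value == 0:
        raise ValueError("initial readout must be nonzero")
    r0 = readout_value * system.d  # d is unit norm, so Ehat(0) = readout_value
    N = system.N
    A_with = -np.eye(N) + state.Omega - np.outer(system.kPC, state.wPC)
    A_without = -np.eye(N) + state.Omega
    drifts = []
    for A in (A_with, A_without):
        rT = expm(A * horizon) @ r0
        drifts.append(abs(float(system.d @ rT) - readout_value) / abs(readout_value))
    drift_with, drift_without = drifts
    return drift_with, drift_without, drift_without - drift_with


@dataclass(frozen=True)
class IntegratorDiagnostics:
    """Summary of the circuit's dynamical tuning."""

    lambda_max_Omega: float
    loop_gain: float
    tau_eff: float


def integrator_diagnostics(state: IntegratorState, system: IntegratorSystem) -> IntegratorDiagnostics:
    """Leading recurrent eigenvalue, cerebellar loop gain, and the
    effective time constant of the readout mode.

    ``tau_eff = tau / |1 - λ_eff|`` where ``λ_eff`` is the leading
    eigenvalue of the effective recurrent matrix ``Ω - kPC·wPC⊤``;
    a perfectly tuned line attractor (``λ_eff = 1``) reports infinity.
    """
    lambda_max = float(np.linalg.eigvals(state.Omega).real.max())
    loop_gain = float(state.wPC @ system.kPC)
    lam_eff = float(np.linalg.eigvals(state.Omega - np.outer(system.kPC, state.wPC)).real.max())
    gap = abs(1.0 - lam_eff)
    tau_eff = math.inf if gap < 1e-15 else system.tau / gap
    return IntegratorDiagnostics(lambda_max_Omega=lambda_max, loop_gain=loop_gain, tau_eff=tau_eff)
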