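"""Lyapunov candidates, analytic derivatives and stability boundaries.

For the gain-tracking circuit the candidate energies are

* ``L1 = ½ W~²`` — single-stage model (only the early gain learns),
* ``L  = ½ (W~² + w~2²)`` — two-stage model, equal weighting,
* ``Lb = ½ (W~² + b·w~2²)`` — reweighted consolidation error, ``b > 0``.

Along trajectories of the learning rules the derivative of ``Lb`` is

    dLb/dt = -eta1·rin²·[(1-α)W~² + α(1-b)·W~·w~2 + α·b·w~2²] - eta1·W~·rin·ξ

with ``α = eta2/eta1``.  Bounding the perturbation term by its
signal-dependent envelope ``|ξ| <= mu |e|`` turns the bracket into a
quadratic form in ``(W~, w~2)``; learning is certified stable wherever
that form is positive semidefinite.  The critical learning-rate ratio is
found by bisecting on the semidefiniteness of this form, which for
``b = 1`` reproduces the closed form ``α_c = 1 - mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .toy_model import Trajectory

__all__ = [
    "LyapunovSpec",
    "StabilityVerdict",
    "WorstCasePerturbation",
    "lyap_value",
    "ldot_toy_analytic",
    "critical_mu_single_stage",
    "critical_alpha_toy",
    "violation_boundary",
    "certify_trajectory",
    "bisect_semidefinite",
]

_VARIANTS = ("L1", "L", "Lb")

#: direction-grid resolution for the semidefiniteness scan
_N_DIRECTIONS = 720
#: slack allowed in the semidefiniteness test (handles the degenerate boundary)
_PSD_SLACK = 1e-12


@dataclass(frozen=True)
class LyapunovSpec:
    """Selects a Lyapunov candidate; ``b`` only applies to ``Lb``."""

    variant: str = "L"
    b: float = 1.0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "Lb" and self.b <= 0:
            raise ValueError("b must be positive for variant Lb")

    @property
    def weight(self) -> float:
        """Consolidation-error weight implied by the variant."""
        if self.variant == "L1":
            return 0.0
        if self.variant == "L":
            return 1.0
        return self.b


@dataclass(frozen=True)
class StabilityVerdict:
    """Critical learning-rate ratio and how it was obtained."""

    alpha_critical: float
    method: str
    tolerance: float


def lyap_value(W_tilde, w2_tilde, spec: LyapunovSpec | None = None):
    """Evaluate the selected Lyapunov candidate.

    ``L1`` ignores ``w2_tilde``; ``Lb`` weights it by ``b``.
    """
    spec = spec or LyapunovSpec()
    W_tilde = np.asarray(W_tilde, dtype=float)
    w2_tilde = np.asarray(w2_tilde, dtype=float)
    return (0.5 * (W_tilde**2 + spec.weight * w2_tilde**2))[()]


def ldot_toy_analytic(
    W_tilde,
    w2_tilde,
    rin_value,
    xi_value,
    eta1: float,
    alpha: float,
    b: float = 1.0,
):
    """Analytic time derivative of ``Lb`` along the two-stage rules."""
    W = np.asarray(W_tilde, dtype=float)
    w2 = np.asarray(w2_tilde, dtype=float)
    rin2 = np.asarray(rin_value, dtype=float) ** 2
    bracket = (1 - alpha) * W**2 + alpha * (1 - b) * W * w2 + alpha * b * w2**2
    return (-eta1 * rin2 * bracket - eta1 * W * np.asarray(rin_value) * np.asarray(xi_value))[()]


def _is_psd(M: np.ndarray, tol: float = _PSD_SLACK) -> bool:
    """Positive-semidefiniteness via eigenvalues plus a unit-circle scan.

    The redundant direction grid guards against conditioning issues at
    the degenerate boundary where an eigenvalue crosses zero.
    """
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if np.linalg.eigvalsh(M).min() < -tol:
        return False
    if M.shape[0] == 2:
        theta = np.linspace(0.0, np.pi, _N_DIRECTIONS, endpoint=False)
        u = np.stack([np.cos(theta), np.sin(theta)])
        vals = np.einsum("ik,ij,jk->k", u, M, u)
        if vals.min() < -tol:
            return False
    return True


def bisect_semidefinite(form, lo: float = 0.0, hi_start: float = 1.0,
                        hi_max: float = 1e6, tol: float = 1e-8) -> float:
    """Largest ``x >= lo`` such that ``form(x)`` is PSD, by bisection.

    ``form`` maps a scalar to a symmetric matrix (1x1 or 2x2) that is PSD
    on an interval ``[lo, x_c]``.  Returns ``lo`` if even ``form(lo)``
    fails; returns ``hi_max`` if the form never loses semidefiniteness
    below it.
    """
    if not _is_psd(form(lo)):
        return lo
    hi = hi_start
    while _is_psd(form(hi)):
        hi *= 2.0
        if hi > hi_max:
            return hi_max
    lo_b = lo
    while hi - lo_b > tol:
        mid = 0.5 * (lo_b + hi)
        if _is_psd(form(mid)):
            lo_b = mid
        else:
            hi = mid
    return 0.5 * (lo_b + hi)


def _toy_bound_form(alpha: float, mu: float, b: float) -> np.ndarray:
    """Quadratic form (in ``(W~, w~2)``) whose positive semidefiniteness
    certifies the worst-case ``dLb/dt`` bound non-positive.

    The worst-case perturbation at the envelope contributes ``+mu W~²``
    after bounding, so the certified bracket is
    ``(1-α-mu)W~² + α(1-b)W~w~2 + αb w~2²``.
    """
    return np.array(
        [
            [1.0 - alpha - mu, 0.5 * alpha * (1.0 - b)],
            [0.5 * alpha * (1.0 - b), alpha * b],
        ]
    )


def critical_mu_single_stage(method: str = "bisection_psd", tol: float = 1e-8) -> StabilityVerdict:
    """Largest perturbation fraction with a single-stage stability guarantee.

    The worst-case bound is ``dL1/dt <= -eta1·rin²·(1-mu)·W~²``; the
    induced (scalar) form is PSD exactly while ``mu <= 1``.
    """
    if method == "closed_form":
        return StabilityVerdict(1.0, method, 0.0)
    if method != "bisection_psd":
        raise ValueError(f"unknown method {method!r}")
    mu_c = bisect_semidefinite(lambda mu: np.array([[1.0 - mu]]), tol=tol)
    return StabilityVerdict(mu_c, method, tol)


def critical_alpha_toy(
    mu: float, b: float = 1.0, method: str = "bisection_psd", tol: float = 1e-8
) -> StabilityVerdict:
    """Critical learning-rate ratio ``α_c`` for the two-stage circuit.

    Returns the supremum of ``α >= 0`` for which the worst-case bound on
    ``dLb/dt`` (perturbation at its envelope with adversarial sign) is
    non-positive over the whole ``(W~, w~2)`` plane.  For ``b = 1`` this
    is ``1 - mu`` (clipped at 0); for general ``b`` the cross term caps
    the certificate at ``4b(1-mu)/(1+b)² <= 1 - mu``.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if b <= 0:
        raise ValueError("b must be positive")
    if method == "closed_form":
        return StabilityVerdict(max(0.0, 4 * b * (1 - mu) / (1 + b) ** 2), method, 0.0)
    if method == "grid_scan":
        alphas = np.linspace(0, 2, 20001)
        ok = [a for a in alphas if _is_psd(_toy_bound_form(a, mu, b))]
        return StabilityVerdict(max(ok) if ok else 0.0, method, float(alphas[1]))
    if method != "bisection_psd":
        raise ValueError(f"unknown method {method!r}")
    alpha_c = bisect_semidefinite(lambda a: _toy_bound_form(a, mu, b), tol=tol)
    return StabilityVerdict(alpha_c, method, tol)


def violation_boundary(alpha: float, alpha_c: float) -> float:
    """Slope ``|w~2| / |W~|`` bounding the region where the worst-case
    ``dL/dt`` bound turns positive (``b = 1``).

    For ``alpha <= alpha_c`` the region is empty and 0 is returned.  The
    slope grows with ``alpha`` and approaches 1 from below.
    """
    if alpha_c < 0:
        raise ValueError("alpha_c must be non-negative")
    if alpha <= alpha_c:
        return 0.0
    return math.sqrt((alpha - alpha_c) / alpha)


class WorstCasePerturbation:
    """Signal-dependent perturbation at its envelope with the adversarial
    sign: ``xi = -mu·e``, which maximizes ``dL/dt`` along trajectories
    (it turns the cross term ``-eta1·W~·rin·ξ`` into ``+eta1·mu·e²``).
    """

    class _Model:
        kind = "signal_dependent_worst_case"
        frequency = 0.0

        def __init__(self, mu: float):
            self.mu = mu

        def to_dict(self) -> dict:
            return {"kind": self.kind, "mu": self.mu}

    def __init__(self, mu: float):
        if mu < 0:
            raise ValueError("mu must be non-negative")
        self.mu = mu
        self.model = self._Model(mu)

    signal_dependent = True

    def __call__(self, t: float, e: float = 0.0) -> float:
        return -self.mu * e


def certify_trajectory(
    traj: Trajectory, spec: LyapunovSpec | None = None, tolerance: float = 1e-6
):
    """Numerically certify monotone decrease of L along a trajectory.

    Computes centered finite-difference dL/dt at every interior sample
    and reports ``(max_violation, certified)`` where certified means the
    maximum does not exceed ``tolerance``.  The trajectory must be
    sampled densely enough for the O(step²) differencing error to sit
    below the tolerance.
    """
    if len(traj.t) < 3:
        raise ValueError("need at least 3 samples to finite-difference L")
    spec = spec or LyapunovSpec()
    L = lyap_value(traj.gain_error, traj.consolidation_error, spec)
    dLdt = (L[2:] - L[:-2]) / (traj.t[2:] - traj.t[:-2])
    max_violation = float(dLdt.max())
    return max_violation, max_violation <= tolerance
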