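import math

import numpy as np
import pytest

from consolidyn import (
    IntegratorState,
    NISolverConfig,
    WorstCasePerturbation,
    build_system,
    classify_consolidation,
    critical_alpha_NI,
    inactivation_probe,
    integrator_diagnostics,
    ldot_NI_analytic,
    learning_rhs,
    lyapunov_NI,
    make_saccade_train,
    network_rhs,
    retinal_slip_rate,
    simulate_consolidation,
)


class TestBuildSystem:
    @pytest.mark.parametrize("N,c,seed", [(2, 1.0, 0), (5, 0.8, 3), (20, 0.9, 7)])
    def test_construction_invariants(self, N, c, seed):
        system, state = build_system(N=N, c_align_target=c, lambda0=1.05, seed=seed)
        assert system.d @ system.ksacc == pytest.approx(1.0, abs=1e-12)
        assert system.c_align == pytest.approx(c, abs=1e-12)
        assert np.linalg.norm(system.d) == pytest.approx(1.0)
        assert np.linalg.norm(system.kPC) == pytest.approx(1.0)
        assert np.abs(np.diag(state.Omega)).max() == 0.0
        lam = np.linalg.eigvals(state.Omega)
        assert lam.real.max() == pytest.approx(1.05, abs=1e-10)
        # detuning sits in the readout direction: d is a left eigenvector
        assert np.allclose(state.Omega.T @ system.d, 1.05 * system.d, atol=1e-12)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            build_system(N=1)
        with pytest.raises(ValueError):
            build_system(N=5, c_align_target=0.0)
        with pytest.raises(ValueError):
            build_system(N=5, c_align_target=1.5)


class TestNetworkRhs:
    def test_origin_is_fixed_point(self, small_integrator):
        system, state = small_integrator
        state.r = np.zeros(system.N)
        assert np.all(network_rhs(state, 0.0, system) == 0.0)

    def test_readout_persistence_on_tuned_matrix(self):
        """If d^T Omega = d^T and the cerebellar loop is silent, the
        readout derivative vanishes for any rate vector."""
        system, state = build_system(N=6, c_align_target=0.9, lambda0=1.0, seed=2)
        rng = np.random.default_rng(0)
        state.r = rng.standard_normal(6)
        state.wPC = np.zeros(6)
        rdot = network_rhs(state, 0.0, system)
        assert system.d @ rdot == pytest.approx(0.0, abs=1e-12)

    def test_pure_leak_without_recurrence(self, small_integrator):
        system, state = small_integrator
        state.Omega = np.zeros((5, 5))
        state.wPC = np.zeros(5)
        state.r = np.ones(5)
        assert np.allclose(network_rhs(state, 0.0, system), -np.ones(5))


class TestSlipRate:
    def test_tuned_silent_circuit_has_no_slip(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.0, seed=5)
        state.r = np.random.default_rng(1).standard_normal(4)
        assert retinal_slip_rate(state, 3.7, system) == pytest.approx(0.0, abs=1e-12)

    def test_zero_rates_zero_slip(self, small_integrator):
        system, state = small_integrator
        state.r = np.zeros(5)
        assert retinal_slip_rate(state, 2.0, system) == pytest.approx(0.0, abs=1e-12)

    def test_slip_rate_matches_readout_error_derivative(self, small_integrator):
        """edot equals the finite difference of (Ehat - E) along a short
        simulation."""
        system, state = small_integrator
        sacc = make_saccade_train(mean_interval=5.0, duration=40.0, seed=2)
        traj = simulate_consolidation(
            system, state, sacc, None, duration=30.0,
            solver=NISolverConfig(step=0.01, record_stride=1),
        )
        slip = traj.Ehat - traj.E
        fd = (slip[2:] - slip[:-2]) / (traj.t[2:] - traj.t[:-2])
        # exclude samples adjacent to pulse edges where Isacc jumps
        vel = np.asarray(sacc.velocity(traj.t))
        interior = (vel[2:] == vel[:-2]) & (vel[1:-1] == vel[2:])
        assert np.max(np.abs(fd[interior] - traj.edot[1:-1][interior])) < 1e-4


class TestLearningRhs:
    def test_fixed_points(self, small_integrator):
        system, state = small_integrator
        state.r = np.ones(5)
        state.wPC = np.zeros(5)
        dwPC, dOmega = learning_rhs(state, 0.0, 0.0, system)
        assert np.all(dwPC == 0.0)
        assert np.all(dOmega == 0.0)  # rPC = 0 freezes the late stage

    def test_late_update_is_rank_one_along_kPC(self, small_integrator):
        system, state = small_integrator
        rng = np.random.default_rng(4)
        state.r = rng.standard_normal(5)
        state.wPC = rng.standard_normal(5)
        _, dOmega = learning_rhs(state, 0.3, 0.0, system)
        assert np.linalg.matrix_rank(dOmega, tol=1e-12) == 1
        expected = -system.eta2 * state.rPC() * np.outer(system.kPC, state.r)
        assert np.allclose(dOmega, expected)


class TestLyapunovNI:
    def test_zero_at_consolidated_solution(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.0, seed=5)
        L, gain, consol = lyapunov_NI(state, system)
        assert L == pytest.approx(0.0, abs=1e-24)

    def test_pure_detuning_splits_evenly(self):
        """wPC = 0 with d^T Omega = d^T + delta^T gives L = |delta|^2,
        half from each term."""
        system, state = build_system(N=6, c_align_target=0.9, lambda0=1.0, seed=2)
        rng = np.random.default_rng(9)
        delta = 0.1 * rng.standard_normal(6)
        state.Omega = state.Omega + np.outer(delta, system.d).T
        L, gain, consol = lyapunov_NI(state, system)
        assert gain == pytest.approx(consol)
        assert L == pytest.approx(float(delta @ delta))

    def test_purkinje_rate_identity(self, small_integrator):
        """c * rPC = -edot + (d^T OmegaTilde) r, an algebraic consequence
        of the definitions, holds at arbitrary states."""
        system, state = small_integrator
        rng = np.random.default_rng(2)
        state.r = rng.standard_normal(5)
        state.wPC = 0.3 * rng.standard_normal(5)
        edot = retinal_slip_rate(state, 0.0, system)
        q = float(state.readout_detuning(system) @ state.r)
        assert system.c_align * state.rPC() == pytest.approx(-edot + q, abs=1e-12)

    def test_invariant_to_choice_of_desired_matrix(self, small_integrator):
        """L depends only on d^T Omega - d^T, so it is identical for any
        desired matrix with readout row d^T (verified by translating
        Omega in a direction orthogonal to the readout)."""
        system, state = small_integrator
        rng = np.random.default_rng(6)
        state.r = rng.standard_normal(5)
        state.wPC = rng.standard_normal(5)
        L1 = lyapunov_NI(state, system)[0]
        w = rng.standard_normal(5)
        w -= (system.d @ w) * system.d  # orthogonal to d
        state2 = state.copy()
        state2.Omega = state.Omega + np.outer(w, rng.standard_normal(5))
        # readout projections unchanged
        assert np.allclose(state2.readout_detuning(system), state.readout_detuning(system))
        assert lyapunov_NI(state2, system)[0] == pytest.approx(L1)


class TestLdotNI:
    def test_zero_at_consolidated_state(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.0, seed=5)
        assert ldot_NI_analytic(state, 0.0, 0.0, system) == pytest.approx(0.0, abs=1e-24)

    def test_marginal_case_alpha_equals_c(self):
        system, state = build_system(
            N=4, c_align_target=0.7, lambda0=1.0, seed=5, eta1=1e-2, eta2=0.7e-2
        )
        # alpha = c and the consolidation projection is silent: Ldot = 0
        state.r = np.zeros(4)
        assert ldot_NI_analytic(state, 0.5, 0.0, system) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("N,seed", [(2, 0), (5, 3), (20, 7)])
    def test_matches_finite_difference_along_trajectories(self, N, seed):
        """The closed form agrees with centered finite differences of L,
        jointly validating the sign conventions of all three ODEs."""
        system, state = build_system(
            N=N, c_align_target=0.8, lambda0=1.03, seed=seed, eta1=5e-3, eta2=5e-4
        )
        sacc = make_saccade_train(mean_interval=10.0, duration=160.0, seed=seed)
        h = 0.02
        traj = simulate_consolidation(
            system, state, sacc, None, duration=150.0,
            solver=NISolverConfig(step=h, record_stride=1),
        )
        fd = (traj.L[2:] - traj.L[:-2]) / (2 * h)
        analytic = -system.eta1 * (
            (system.c_align - system.alpha) * traj.edot**2
            + system.alpha * traj.q_proj**2
        )
        # mask stencils that straddle a velocity-pulse edge, where the
        # rate derivative jumps and centered differencing degrades
        vel = np.asarray(sacc.velocity(traj.t))
        smooth = (vel[2:] == vel[:-2]) & (vel[1:-1] == vel[2:])
        scale = max(1e-12, np.abs(analytic).max())
        assert np.max(np.abs((fd - analytic[1:-1])[smooth])) < 0.01 * scale


class TestCriticalAlphaNI:
    def test_parallel_vectors_recover_scalar_circuit_condition(self):
        v = critical_alpha_NI(1.0, 0.0)
        assert v.alpha_critical == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("c", [0.25, 0.5, 0.75, 1.0])
    def test_scales_linearly_in_alignment(self, c):
        assert critical_alpha_NI(c, 0.0).alpha_critical == pytest.approx(c, abs=1e-6)

    def test_guarantee_vanishes_at_full_perturbation(self):
        assert critical_alpha_NI(0.6, 1.0).alpha_critical == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_alignment_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            critical_alpha_NI(0.0, 0.0)


class TestSimulateConsolidation:
    def test_zero_learning_rates_freeze_weights(self):
        system, state = build_system(N=4, c_align_target=0.8, lambda0=1.02, seed=1,
                                     eta1=1e-12, eta2=0.0)
        Omega0 = state.Omega.copy()
        sacc = make_saccade_train(mean_interval=5.0, duration=60.0, seed=1)
        traj = simulate_consolidation(system, state, sacc, None, duration=50.0)
        assert np.allclose(traj.final_state.Omega, Omega0, atol=1e-9)
        assert np.allclose(traj.final_state.wPC, 0.0, atol=1e-9)

    def test_stable_regime_tunes_small_network(self):
        """A 5-neuron run reaches a tuned integrator: the leading
        eigenvalue lands on 1, the slip vanishes and L decays
        monotonically.  (Full emptying of wPC needs the richer
        excitation of larger networks; here it only shrinks.)"""
        system, state = build_system(
            N=5, c_align_target=0.9, lambda0=1.05, seed=3, eta1=5e-3, eta2=5e-4
        )
        sacc = make_saccade_train(mean_interval=20.0, duration=4100.0, seed=3)
        traj = simulate_consolidation(
            system, state, sacc, None, duration=4000.0,
            solver=NISolverConfig(step=0.02, record_stride=100),
        )
        assert not traj.divergent
        assert abs(traj.lambda_max[-1] - 1.0) < 1e-3
        assert traj.wPC_norm[-1] < 0.05 * (1.05 - 1.0)  # well below the detuning scale
        assert traj.L[-1] < 0.1 * traj.L[0]
        # L is non-increasing to solver tolerance
        assert np.max(np.diff(traj.L)) < 1e-8

    def test_too_coarse_step_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            NISolverConfig(step=0.5)


class TestInactivation:
    def test_perfect_integrator_has_zero_drift(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.0, seed=5)
        dw, dwo, dep = inactivation_probe(state, system, horizon=20.0)
        assert dw == pytest.approx(0.0, abs=1e-10)
        assert dep == pytest.approx(0.0, abs=1e-10)

    def test_compensated_state_depends_on_cerebellum(self):
        """When wPC cancels the detuning, removing the cerebellar pathway
        re-exposes the unstable drift."""
        system, state = build_system(N=6, c_align_target=1.0, lambda0=1.05, seed=4)
        # with c=1 (kPC = d), wPC = ((lambda0-1)/c) d cancels the readout
        # detuning: d^T(Omega - kPC wPC^T) = d^T
        state.wPC = (1.05 - 1.0) * system.d
        dw, dwo, dep = inactivation_probe(state, system, horizon=20.0)
        assert dw < 1e-8
        assert dwo > 1.0  # exp(0.05*20)-1 ~ 1.7
        assert dep > 1.0

    def test_zero_readout_rejected(self, small_integrator):
        system, state = small_integrator
        with pytest.raises(ValueError, match="nonzero"):
            inactivation_probe(state, system, readout_value=0.0)


class TestDiagnostics:
    def test_pure_leak(self, small_integrator):
        system, state = small_integrator
        state.Omega = np.zeros((5, 5))
        state.wPC = np.zeros(5)
        diag = integrator_diagnostics(state, system)
        assert diag.lambda_max_Omega == 0.0
        assert diag.loop_gain == 0.0
        assert diag.tau_eff == pytest.approx(system.tau)

    def test_line_attractor_reports_infinite_time_constant(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.0, seed=5)
        assert integrator_diagnostics(state, system).tau_eff == math.inf

    def test_unstable_mode_growth_time_constant(self):
        system, state = build_system(N=4, c_align_target=0.7, lambda0=1.05, seed=5, tau=1.0)
        diag = integrator_diagnostics(state, system)
        assert diag.tau_eff == pytest.approx(20.0, rel=1e-6)
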