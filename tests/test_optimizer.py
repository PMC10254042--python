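import numpy as np
import pytest

from conftest import random_hermitian
from rpcontrol.liouville import FreePropagator
from rpcontrol.optimizer import (
    GYRO_SCALE,
    ControlConfig,
    apply_seed_kick,
    optimize_coherent,
    optimize_coherent_batch,
    optimize_ensemble,
)
from rpcontrol.spin_core import (
    RadicalPairSystem,
    control_operator,
    hamiltonian,
    initial_singlet_state,
    projector,
    singlet_projector,
    state_vector,
)
from rpcontrol.targets import MovingTarget, build_anisotropic_target


class TestConfig:
    def test_rejects_negative_amplitude(self):
        with pytest.raises(ValueError):
            ControlConfig(amplitude=-1.0, t_f=1.0)

    def test_rejects_bad_tf(self):
        with pytest.raises(ValueError):
            ControlConfig(amplitude=1.0, t_f=0.0)

    def test_output_grid(self):
        cfg = ControlConfig(amplitude=1.0, t_f=1.0, output_step_ns=0.5)
        times = cfg.output_times()
        assert len(times) == 2001
        assert times[-1] == pytest.approx(1.0)


class TestSeedKick:
    def test_zero_angle_is_identity(self, rho0):
        np.testing.assert_allclose(apply_seed_kick(rho0, 0.0), rho0)

    def test_second_order_singlet_perturbation(self, rho0):
        p = singlet_projector()
        for angle in (1e-2, 1e-3):
            kicked = apply_seed_kick(rho0, angle)
            delta = 1.0 - np.einsum("ij,ij->", p.conj(), kicked).real
            assert 0 < delta < 2.0 * angle**2

    def test_preserves_density_matrix(self, rho0):
        kicked = apply_seed_kick(rho0, 0.1)
        assert np.trace(kicked).real == pytest.approx(1.0)
        np.testing.assert_allclose(kicked, kicked.conj().T, atol=1e-14)


class TestZeroAmplitudeLimit:
    def test_matches_free_propagation(self, powder_system, rho0):
        s = powder_system.with_euler((0.0, 0.6, 0.0))
        h = hamiltonian(s)
        tgt = build_anisotropic_target(s).projector
        cfg = ControlConfig(amplitude=0.0, t_f=0.3, output_step_ns=1.0,
                            seed_kick=0.0)
        res = optimize_ensemble([h], control_operator(s), [tgt], [1.0],
                                rho0, cfg, k_s=s.k_s)
        assert np.max(np.abs(res.u)) == 0.0
        exact = FreePropagator(h, k_s=s.k_s).at(rho0, 0.3)
        np.testing.assert_allclose(res.final_states[0], exact, atol=1e-7)

    def test_eigenvalues_conserved_without_drive_or_reaction(
        self, lowfield_system, rho0
    ):
        h = hamiltonian(lowfield_system)
        mt = MovingTarget([(1.0, "S")], 0.5, h)
        cfg = ControlConfig(amplitude=0.0, t_f=0.5, output_step_ns=1.0,
                            seed_kick=0.0)
        res = optimize_coherent(h, control_operator(lowfield_system), mt,
                                rho0, cfg)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(res.final_states[0])),
            np.sort(np.linalg.eigvalsh(rho0)), atol=1e-8,
        )


class TestSymmetryFixedPoint:
    def test_unkicked_coherent_field_stays_zero(self, highfield_system, rho0):
        # exact pi-rotation symmetry: without the seed kick u == 0 forever
        h = hamiltonian(highfield_system)
        mt = MovingTarget([(0.8, "T+-"), (1.0, "S")], 0.2, h)
        cfg = ControlConfig(amplitude=1.0, t_f=0.2, output_step_ns=1.0,
                            seed_kick=0.0)
        res = optimize_coherent(h, control_operator(highfield_system), mt,
                                rho0, cfg)
        assert np.max(np.abs(res.u)) < 1e-8

    def test_kick_ignites_transfer(self, highfield_system, rho0):
        h = hamiltonian(highfield_system)
        mt = MovingTarget([(0.8, "T+-"), (1.0, "S")], 1.0, h)
        cfg = ControlConfig(amplitude=1.85, t_f=1.0, output_step_ns=0.5,
                            seed_kick=0.01)
        res = optimize_coherent(h, control_operator(highfield_system), mt,
                                rho0, cfg)
        assert np.max(np.abs(res.u)) > 0.05
        assert res.final_fidelity > 0.8


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(10))
    def test_random_systems_monotone_y(self, seed, rho0):
        # moving-target control with k_s = 0: y must never decrease
        rng = np.random.default_rng(seed)
        h = random_hermitian(rng, scale=100.0)
        v = control_operator(RadicalPairSystem())
        kets = [state_vector("T+a"), state_vector("Sb")]
        target = projector([kets[0]]) + 0.5 * projector([kets[1]])
        mt = MovingTarget([(1.0, target)], 0.2, h)
        cfg = ControlConfig(amplitude=rng.uniform(0.5, 2.0), t_f=0.2,
                            output_step_ns=1.0, seed_kick=0.02)
        res = optimize_coherent(h, v, mt, rho0, cfg)
        assert np.min(np.diff(res.y)) > -1e-8

    def test_gradient_identity(self, lowfield_system, rho0):
        # dy/dt == A [<target|L_V|rho>]^2: with u = (A/gyro) * g this is
        # dy/dt == u^2 * gyro / A, checked by finite differences
        h = hamiltonian(lowfield_system)
        mt = MovingTarget([(0.89, "T+a,T-b"), (0.93, "S")], 1.0, h)
        a_mT = 1.1
        cfg = ControlConfig(amplitude=a_mT, t_f=1.0, output_step_ns=0.5)
        res = optimize_coherent(h, control_operator(lowfield_system), mt,
                                rho0, cfg)
        dy = np.gradient(res.y, res.times)
        expected = res.u**2 * GYRO_SCALE / a_mT
        scale = np.max(expected)
        np.testing.assert_allclose(dy, expected, atol=5e-3 * scale)


class TestIntegrationAccuracy:
    def test_tolerance_refinement_converged(self, highfield_system, rho0):
        h = hamiltonian(highfield_system)
        v = control_operator(highfield_system)
        mt = MovingTarget([(0.8, "T+-"), (1.0, "S")], 0.25, h)
        finals = []
        for rtol in (1e-8, 1e-9):
            cfg = ControlConfig(amplitude=1.0, t_f=0.25, output_step_ns=1.0,
                                rtol=rtol, atol=rtol * 1e-2)
            res = optimize_coherent(h, v, mt, rho0, cfg)
            finals.append(res.y[-1])
        assert abs(finals[1] - finals[0]) < 1e-6

    def test_batch_matches_single(self, highfield_system, rho0):
        h = hamiltonian(highfield_system)
        v = control_operator(highfield_system)
        params = [(0.7, 1.1, 1.5), (0.85, 0.95, 0.8)]
        mts = [MovingTarget([(qt, "T+-"), (qs, "S")], 0.5, h)
               for qt, qs, _ in params]
        cfg = ControlConfig(amplitude=1.0, t_f=0.5, output_step_ns=0.5)
        fids = optimize_coherent_batch(
            h, v, mts, [p[2] for p in params], rho0, cfg
        )
        for i, (qt, qs, a) in enumerate(params):
            single = optimize_coherent(
                h, v, MovingTarget([(qt, "T+-"), (qs, "S")], 0.5, h), rho0,
                ControlConfig(amplitude=a, t_f=0.5, output_step_ns=0.5),
            )
            assert fids[i] == pytest.approx(single.final_fidelity, abs=2e-6)


class TestEnsembleControl:
    def test_trace_nonincreasing_with_reaction(self, powder_system, rho0):
        s = powder_system.with_euler((0.0, 0.8, 0.0))
        h = hamiltonian(s)
        tgt = build_anisotropic_target(s).projector
        cfg = ControlConfig(amplitude=3.0, t_f=0.5, output_step_ns=0.5)
        res = optimize_ensemble([h], control_operator(s), [tgt], [1.0],
                                rho0, cfg, k_s=s.k_s)
        assert np.all(np.diff(res.populations["trace"][0]) <= 1e-9)

    def test_mismatched_targets_rejected(self, powder_system, rho0):
        s = powder_system.with_euler((0.0, 0.8, 0.0))
        h = hamiltonian(s)
        cfg = ControlConfig(amplitude=1.0, t_f=0.1)
        with pytest.raises(ValueError):
            optimize_ensemble([h], control_operator(s), [], [], rho0, cfg)

    def test_single_orientation_transfer_saturates(self, rho0):
        # no-hyperfine reduction (exaggerated delta-g toy): S -> T+ and
        # S -> T- are equally resonant under the linear drive, so the
        # transfer into the T+a/T-b target saturates at exactly 1/2
        s = RadicalPairSystem(g_a=2.000, g_b=2.2, b0=3.6, j_exchange=0.0)
        h = hamiltonian(s)
        tgt = build_anisotropic_target(s).projector
        cfg = ControlConfig(amplitude=3.0, t_f=2.0, output_step_ns=0.5,
                            seed_kick=0.01)
        res = optimize_ensemble([h], control_operator(s), [tgt], [1.0],
                                rho0, cfg, k_s=0.0)
        assert np.min(np.diff(res.y)) > -1e-8
        assert res.y[-1] == pytest.approx(0.5, abs=0.01)
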