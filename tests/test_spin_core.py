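import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpcontrol.constants import (
    CONSTANTS,
    MHz_to_mT,
    mT_to_MHz,
    rad_per_us_to_MHz,
)
from rpcontrol.spin_core import (
    BASIS_LABELS,
    DIM,
    RadicalPairSystem,
    control_operator,
    euler_rotation_matrix,
    hamiltonian_iso,
    hamiltonian_lab,
    initial_singlet_state,
    projector,
    resonance_frequencies,
    rotate_hyperfine,
    singlet_projector,
    spin_operators,
    state_vector,
)

angles = st.floats(-10.0, 10.0, allow_nan=False)


class TestConstants:
    def test_bohr_magneton_over_planck(self):
        assert CONSTANTS.bohr_magneton / CONSTANTS.planck == pytest.approx(
            1.3996e10, rel=1e-4
        )

    def test_positive(self):
        with pytest.raises(ValueError):
            type(CONSTANTS)(bohr_magneton=-1.0)

    def test_mT_MHz_round_trip(self):
        b = 0.54
        assert MHz_to_mT(mT_to_MHz(b, 2.0), 2.0) == pytest.approx(b, rel=1e-10)

    def test_054_mT_is_about_15_MHz(self):
        # the paper's quoted equivalence at g ~ 2
        assert mT_to_MHz(0.54, 2.0) == pytest.approx(15.1, abs=0.1)


class TestSpinOperators:
    def test_traceless(self):
        ops = spin_operators()
        for op in (ops.sz_a, ops.sz_b, ops.iz, ops.sx_a, ops.sy_b):
            assert abs(np.trace(op)) < 1e-14

    def test_su2_commutators(self):
        ops = spin_operators()
        for x, y, z in [
            (ops.sx_a, ops.sy_a, ops.sz_a),
            (ops.sx_b, ops.sy_b, ops.sz_b),
            (ops.ix, ops.iy, ops.iz),
        ]:
            np.testing.assert_allclose(x @ y - y @ x, 1j * z, atol=1e-14)

    def test_distinct_particles_commute(self):
        ops = spin_operators()
        for a in (ops.sx_a, ops.sz_a):
            for b in (ops.sy_b, ops.iz):
                np.testing.assert_allclose(a @ b - b @ a, 0.0, atol=1e-14)

    def test_spin_half_square(self):
        ops = spin_operators()
        np.testing.assert_allclose(
            ops.sz_a @ ops.sz_a, 0.25 * np.eye(DIM), atol=1e-14
        )

    def test_hermitian(self):
        ops = spin_operators()
        for op in (ops.sx_a, ops.sy_a, ops.sz_a, ops.ix, ops.iy, ops.iz):
            np.testing.assert_allclose(op, op.conj().T, atol=1e-14)


class TestEulerRotation:
    def test_zero_angles_identity(self):
        np.testing.assert_allclose(
            euler_rotation_matrix(0, 0, 0), np.eye(3), atol=1e-15
        )

    @settings(max_examples=50, deadline=None)
    @given(angles, angles, angles)
    def test_orthogonal_unit_determinant(self, a, b, g):
        r = euler_rotation_matrix(a, b, g)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)

    def test_beta_90(self):
        # molecular z maps onto lab -x for (0, pi/2, 0)
        r = euler_rotation_matrix(0.0, np.pi / 2, 0.0)
        expected = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        np.testing.assert_allclose(r, expected, atol=1e-15)


class TestRotateHyperfine:
    def test_identity_rotation(self):
        a = rotate_hyperfine((1.0, 2.0, 3.0), (0, 0, 0))
        np.testing.assert_allclose(a, np.diag([1.0, 2.0, 3.0]), atol=1e-14)

    @settings(max_examples=50, deadline=None)
    @given(angles, angles, angles)
    def test_eigenvalues_and_trace_preserved(self, al, be, ga):
        principal = (1.2, 1.2, 1.8)
        a = rotate_hyperfine(principal, (al, be, ga))
        np.testing.assert_allclose(a, a.T, atol=1e-12)
        np.testing.assert_allclose(
            np.sort(np.linalg.eigvalsh(a)), np.sort(principal), atol=1e-10
        )
        assert np.trace(a) == pytest.approx(sum(principal), abs=1e-10)

    def test_beta_90_swaps_zz(self):
        a = rotate_hyperfine((1.2, 1.2, 1.8), (0, np.pi / 2, 0))
        assert a[2, 2] == pytest.approx(1.2, abs=1e-12)


class TestHamiltonians:
    def test_all_zero(self):
        s = RadicalPairSystem(g_a=2.0, g_b=2.0, b0=0.0)
        np.testing.assert_allclose(hamiltonian_lab(s), 0.0, atol=1e-14)

    def test_larmor_frequency(self):
        s = RadicalPairSystem(g_a=2.0023, g_b=2.0023, b0=1.0)
        freqs = [f for f, *_ in resonance_frequencies(hamiltonian_lab(s))]
        # electron Larmor g mu_B B / h = 28.02 MHz at 1 mT
        assert min(abs(f - 28.02) for f in freqs) < 0.01

    def test_radical_b_resonance(self, powder_system):
        h = hamiltonian_lab(powder_system.with_euler((0.0, 0.0, 0.0)))
        lines = resonance_frequencies(h, control_operator(powder_system))
        strong = [f for f, _, _, w in lines if w > 0.1 * max(l[3] for l in lines)]
        assert min(abs(f - 100.9) for f in strong) < 0.5

    def test_hermitian(self, powder_system, rng):
        for _ in range(5):
            s = powder_system.with_euler(rng.uniform(0, np.pi, 3))
            h = hamiltonian_lab(s)
            np.testing.assert_allclose(h, h.conj().T, atol=1e-10)

    def test_iso_matches_lab_at_equivalent_field(self):
        iso = RadicalPairSystem(g_a=2.0, g_b=2.0, b0=3.0, a_iso_MHz=15.0)
        b_eq = MHz_to_mT(15.0, 2.0)
        lab = RadicalPairSystem(
            g_a=2.0, g_b=2.0, b0=3.0, hyperfine_principal=(b_eq,) * 3
        )
        np.testing.assert_allclose(
            hamiltonian_iso(iso), hamiltonian_lab(lab), atol=1e-8
        )

    def test_singlet_eigenstate_when_symmetric(self):
        s = RadicalPairSystem(g_a=2.0, g_b=2.0, b0=5.0, a_iso_MHz=0.0,
                              j_exchange=0.0)
        h = hamiltonian_iso(s)
        v = state_vector("Sa")
        hv = h @ v
        # H|S> is proportional to |S>
        overlap = np.vdot(v, hv)
        np.testing.assert_allclose(hv, overlap * v, atol=1e-10)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            RadicalPairSystem(b0=np.nan)


class TestProjector:
    def test_singlet_projector_trace(self):
        assert np.trace(singlet_projector()).real == pytest.approx(2.0)

    def test_orthogonal_to_t0(self):
        np.testing.assert_allclose(
            singlet_projector() @ state_vector("T0a"), 0.0, atol=1e-14
        )

    def test_initial_state_normalized(self):
        rho0 = initial_singlet_state()
        assert np.trace(rho0).real == pytest.approx(1.0)
        assert np.einsum(
            "ij,ij->", singlet_projector().conj(), rho0
        ).real == pytest.approx(1.0)

    def test_rejects_unnormalized(self):
        with pytest.raises(ValueError):
            projector([2.0 * state_vector("Sa")])

    def test_idempotent(self):
        p = projector([state_vector("T+a"), state_vector("T-b")])
        np.testing.assert_allclose(p @ p, p, atol=1e-14)


class TestResonanceFrequencies:
    def test_zero_hamiltonian(self):
        lines = resonance_frequencies(np.zeros((2, 2)))
        assert all(f == 0.0 for f, *_ in lines)

    def test_two_level_gap(self):
        gap = 3.7  # rad/us
        lines = resonance_frequencies(np.diag([0.0, gap]))
        assert len(lines) == 1
        assert lines[0][0] == pytest.approx(rad_per_us_to_MHz(gap))

    def test_rejects_non_hermitian(self):
        with pytest.raises(ValueError):
            resonance_frequencies(np.array([[0.0, 1.0], [0.0, 0.0]]))


def test_basis_labels_order():
    assert BASIS_LABELS[0] == "Sa" and len(BASIS_LABELS) == DIM
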