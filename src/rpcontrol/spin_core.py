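"""Spin operators, Hamiltonians and frame rotations for a two-electron /
one-nucleus (spin-1/2) radical pair.

Hilbert space dimension is fixed at 8.  The canonical basis ordering used
for every matrix in this package is the electron singlet/triplet product
basis crossed with the nuclear Zeeman basis::

    |S a>, |S b>, |T+ a>, |T+ b>, |T0 a>, |T0 b>, |T- a>, |T- b>

where ``a``/``b`` denote the nuclear alpha/beta states.  Hamiltonians are
returned in angular frequency units (rad/us).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .constants import (
    PROTON_G,
    MHz_to_rad_per_us,
    electron_gyromagnetic,
    mT_to_rad_per_us,
    nuclear_gyromagnetic,
    rad_per_us_to_MHz,
)

DIM = 8

# single spin-1/2 operators
_SX = 0.5 * np.array([[0, 1], [1, 0]], dtype=complex)
_SY = 0.5 * np.array([[0, -1j], [1j, 0]], dtype=complex)
_SZ = 0.5 * np.array([[1, 0], [0, -1]], dtype=complex)
_ID = np.eye(2, dtype=complex)

# electron-pair singlet/triplet states in the product (up/down) basis
_SQ2 = 1.0 / np.sqrt(2.0)
_PAIR_STATES = np.array(
    [
        [0.0, _SQ2, -_SQ2, 0.0],  # |S>  = (ud - du)/sqrt2
        [1.0, 0.0, 0.0, 0.0],     # |T+> = uu
        [0.0, _SQ2, _SQ2, 0.0],   # |T0> = (ud + du)/sqrt2
        [0.0, 0.0, 0.0, 1.0],     # |T-> = dd
    ],
    dtype=complex,
).T  # columns are S, T+, T0, T-

#: index of each combined basis state, e.g. ``BASIS_LABELS.index("T+a")``
BASIS_LABELS = ["Sa", "Sb", "T+a", "T+b", "T0a", "T0b", "T-a", "T-b"]

# unitary mapping the product basis onto the S/T (x) nuclear basis
_U = np.kron(_PAIR_STATES, _ID)


def basis_change() -> np.ndarray:
    """Unitary whose columns are the S/T x nuclear states in the product basis."""
    return _U.copy()


def _embed(op: np.ndarray, slot: int) -> np.ndarray:
    """Place a 2x2 operator on tensor slot 0 (electron A), 1 (B) or 2 (nucleus)."""
    factors = [_ID, _ID, _ID]
    factors[slot] = op
    out = np.kron(np.kron(factors[0], factors[1]), factors[2])
    return _U.conj().T @ out @ _U


@dataclass(frozen=True)
class SpinOperators:
    """The full 8x8 operator set in the canonical basis."""

    sx_a: np.ndarray
    sy_a: np.ndarray
    sz_a: np.ndarray
    sx_b: np.ndarray
    sy_b: np.ndarray
    sz_b: np.ndarray
    ix: np.ndarray
    iy: np.ndarray
    iz: np.ndarray

    def electron(self, which: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if which == "A":
            return self.sx_a, self.sy_a, self.sz_a
        if which == "B":
            return self.sx_b, self.sy_b, self.sz_b
        raise ValueError(f"unknown electron {which!r}")


@lru_cache(maxsize=1)
def spin_operators() -> SpinOperators:
    """Cartesian spin operators for both electrons and the nucleus."""
    return SpinOperators(
        sx_a=_embed(_SX, 0), sy_a=_embed(_SY, 0), sz_a=_embed(_SZ, 0),
        sx_b=_embed(_SX, 1), sy_b=_embed(_SY, 1), sz_b=_embed(_SZ, 1),
        ix=_embed(_SX, 2), iy=_embed(_SY, 2), iz=_embed(_SZ, 2),
    )


def state_vector(label: str) -> np.ndarray:
    """Unit ket for one of the canonical basis labels (e.g. ``"T+a"``)."""
    try:
        idx = BASIS_LABELS.index(label)
    except ValueError as exc:
        raise ValueError(f"unknown basis label {label!r}") from exc
    v = np.zeros(DIM, dtype=complex)
    v[idx] = 1.0
    return v


@dataclass(frozen=True)
class RadicalPairSystem:
    """Physical parameters of the pair at one molecular orientation.

    Fields are in user units: ``b0`` in mT, ``hyperfine_principal`` in mT,
    ``a_iso_MHz`` (isotropic alternative) in MHz, ``j_exchange`` in MHz
    (linear frequency), ``k_s`` in 1/us, Euler angles in radians.
    """

    g_a: float = 2.000
    g_b: float = 2.002
    g_n: float = PROTON_G
    b0: float = 0.0
    hyperfine_principal: tuple[float, float, float] = (0.0, 0.0, 0.0)
    a_iso_MHz: float | None = None
    j_exchange: float = 0.0
    k_s: float = 0.0
    euler: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        vals = [self.g_a, self.g_b, self.g_n, self.b0, self.j_exchange,
                self.k_s, *self.hyperfine_principal, *self.euler]
        if self.a_iso_MHz is not None:
            vals.append(self.a_iso_MHz)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite system parameter")
        if self.b0 < 0:
            raise ValueError("b0 must be >= 0")
        if self.k_s < 0:
            raise ValueError("k_s must be >= 0")

    def with_euler(self, euler: Sequence[float]) -> "RadicalPairSystem":
        return RadicalPairSystem(
            g_a=self.g_a, g_b=self.g_b, g_n=self.g_n, b0=self.b0,
            hyperfine_principal=self.hyperfine_principal,
            a_iso_MHz=self.a_iso_MHz, j_exchange=self.j_exchange,
            k_s=self.k_s, euler=tuple(float(x) for x in euler),
        )


def euler_rotation_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Molecular-to-laboratory rotation matrix R(alpha, beta, gamma)."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    return np.array(
        [
            [cg * cb * ca - sg * sa, cg * cb * sa + sg * ca, -cg * sb],
            [-sg * cb * ca - cg * sa, -sg * cb * sa + cg * ca, sg * sb],
            [sb * ca, sb * sa, cb],
        ]
    )


def rotate_hyperfine(
    principal: Sequence[float], euler: Sequence[float]
) -> np.ndarray:
    """Hyperfine tensor in the laboratory frame, A_L = R diag(A) R^-1 (mT)."""
    principal = np.asarray(principal, dtype=float)
    if not np.all(np.isfinite(principal)):
        raise ValueError("non-finite principal values")
    r = euler_rotation_matrix(*euler)
    return r @ np.diag(principal) @ r.T


def hamiltonian_lab(system: RadicalPairSystem) -> np.ndarray:
    """Lab-frame Hamiltonian with the full anisotropic hyperfine tensor.

    Sum of both electron Zeeman terms, the nuclear Zeeman term, the
    anisotropic hyperfine coupling S_A . A_L . I and the exchange term
    -J(1/2 + 2 S_A.S_B).  Returned in rad/us.
    """
    ops = spin_operators()
    a_lab = rotate_hyperfine(system.hyperfine_principal, system.euler)
    # the mT-valued tensor couples through radical A's gyromagnetic ratio
    a_omega = a_lab * electron_gyromagnetic(system.g_a)
    s_a = (ops.sx_a, ops.sy_a, ops.sz_a)
    nuc = (ops.ix, ops.iy, ops.iz)
    h = mT_to_rad_per_us(system.b0, system.g_a) * ops.sz_a
    h = h + mT_to_rad_per_us(system.b0, system.g_b) * ops.sz_b
    h = h + nuclear_gyromagnetic(system.g_n) * system.b0 * ops.iz
    for i in range(3):
        for j in range(3):
            if a_omega[i, j] != 0.0:
                h = h + a_omega[i, j] * (s_a[i] @ nuc[j])
    h = h + _exchange_term(system.j_exchange)
    if not np.all(np.isfinite(h)):
        raise ValueError("non-finite Hamiltonian")
    return h


def hamiltonian_iso(system: RadicalPairSystem) -> np.ndarray:
    """Isotropic-hyperfine Hamiltonian, a_A S_A.I instead of the tensor."""
    if system.a_iso_MHz is None:
        raise ValueError("system.a_iso_MHz is not set")
    ops = spin_operators()
    a = MHz_to_rad_per_us(system.a_iso_MHz)
    h = mT_to_rad_per_us(system.b0, system.g_a) * ops.sz_a
    h = h + mT_to_rad_per_us(system.b0, system.g_b) * ops.sz_b
    h = h + nuclear_gyromagnetic(system.g_n) * system.b0 * ops.iz
    h = h + a * (ops.sx_a @ ops.ix + ops.sy_a @ ops.iy + ops.sz_a @ ops.iz)
    h = h + _exchange_term(system.j_exchange)
    return h


def _exchange_term(j_MHz: float) -> np.ndarray:
    ops = spin_operators()
    dot = ops.sx_a @ ops.sx_b + ops.sy_a @ ops.sy_b + ops.sz_a @ ops.sz_b
    return -MHz_to_rad_per_us(j_MHz) * (0.5 * np.eye(DIM) + 2.0 * dot)


def hamiltonian(system: RadicalPairSystem) -> np.ndarray:
    """Dispatch to the isotropic or tensor Hamiltonian."""
    if system.a_iso_MHz is not None:
        return hamiltonian_iso(system)
    return hamiltonian_lab(system)


def control_operator(system: RadicalPairSystem) -> np.ndarray:
    """Coupling operator of a linearly polarized RF field along lab x.

    V = (g_A mu_B / hbar) Sx_A + (g_B mu_B / hbar) Sx_B, in rad/us per mT,
    so u(t) in mT times V gives an angular-frequency Hamiltonian term.
    There is no nuclear drive term.
    """
    ops = spin_operators()
    return (
        electron_gyromagnetic(system.g_a) * ops.sx_a
        + electron_gyromagnetic(system.g_b) * ops.sx_b
    )


def projector(states: np.ndarray | Sequence[np.ndarray]) -> np.ndarray:
    """Sum of projectors onto the given normalized kets."""
    states = np.atleast_2d(np.asarray(states, dtype=complex))
    norms = np.linalg.norm(states, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("projector states must be normalized")
    return np.einsum("ki,kj->ij", states, states.conj())


def singlet_projector() -> np.ndarray:
    """P_S = |S><S| (x) identity on the nuclear factor; trace 2."""
    return projector([state_vector("Sa"), state_vector("Sb")])


def initial_singlet_state() -> np.ndarray:
    """rho(0) = (|S><S| (x) I_nuc) / 2: singlet-born, unpolarized nucleus."""
    return singlet_projector() / 2.0


def resonance_frequencies(
    h: np.ndarray, transition_operator: np.ndarray | None = None
) -> list[tuple[float, int, int, float]]:
    """All eigenvalue-difference transition lines of a Hermitian matrix.

    Returns tuples ``(frequency_MHz, i, j, intensity)`` sorted by
    frequency; intensity is |<i|V|j>|^2 for the supplied transition
    operator (1.0 for all lines when none is given).  Serves as a native
    stick spectrum to annotate waveform FFT peaks.
    """
    h = np.asarray(h)
    if not np.allclose(h, h.conj().T, atol=1e-9):
        raise ValueError("resonance_frequencies expects a Hermitian matrix")
    w, vecs = np.linalg.eigh(h)
    lines = []
    v_eig = None
    if transition_operator is not None:
        v_eig = vecs.conj().T @ transition_operator @ vecs
    n = len(w)
    for i in range(n):
        for j in range(i + 1, n):
            freq = rad_per_us_to_MHz(abs(w[j] - w[i]))
            inten = 1.0 if v_eig is None else float(abs(v_eig[i, j]) ** 2)
            lines.append((freq, i, j, inten))
    lines.sort(key=lambda t: t[0])
    return lines
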