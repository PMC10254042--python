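"""Liouville-space machinery: vectorization, superoperators, free propagation.

Convention: column-stacking vectorization, so that the inner product
``<<A|B>> = vec(A)^dagger vec(B) = Tr(A^dagger B)`` and the performance
index reads literally as y = <P|rho>.  Equations of motion are written
as ``d|rho>/dt = -i L |rho>`` with L = L0 + u(t) L_V + L_K, where L_K
carries the Haberkorn reaction term (anti-Hermitian part).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .spin_core import DIM, singlet_projector

LDIM = DIM * DIM


class PhysicalityError(RuntimeError):
    """Raised when a propagated state stops being a density operator."""


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Column-stack an 8x8 matrix into a 64-vector."""
    matrix = np.asarray(matrix)
    if matrix.shape != (DIM, DIM):
        raise ValueError(f"expected {DIM}x{DIM} matrix, got {matrix.shape}")
    return matrix.reshape(-1, order="F").astype(complex)


def devectorize(vec: np.ndarray) -> np.ndarray:
    vec = np.asarray(vec)
    if vec.shape != (LDIM,):
        raise ValueError(f"expected length-{LDIM} vector, got {vec.shape}")
    return vec.reshape(DIM, DIM, order="F")


def inner_product(a: np.ndarray, b: np.ndarray) -> complex:
    """<<a|b>> = Tr(A^dagger B) for vectorized matrices."""
    return complex(np.vdot(a, b))


@dataclass(frozen=True)
class Superoperator:
    """A 64x64 linear map acting on vectorized density operators."""

    matrix: np.ndarray
    kind: str  # "static" | "control" | "reaction"

    def __matmul__(self, vec: np.ndarray) -> np.ndarray:
        return self.matrix @ vec


def commutator_superop(h: np.ndarray, kind: str = "static") -> Superoperator:
    """L = H (x) left - H (x) right, i.e. L vec(rho) = vec(H rho - rho H)."""
    h = np.asarray(h, dtype=complex)
    if h.shape != (DIM, DIM):
        raise ValueError("commutator_superop expects an 8x8 matrix")
    ident = np.eye(DIM)
    mat = np.kron(ident, h) - np.kron(h.T, ident)
    return Superoperator(matrix=mat, kind=kind)


def haberkorn_superop(k_s: float) -> Superoperator:
    """Singlet-recombination superoperator L_K = -i k_s/2 (P_S left + P_S right).

    Inserted into ``d|rho>/dt = -i L |rho>`` it contributes the
    anticommutator drain ``-k_s/2 {P_S, rho}``.  ``k_s`` in 1/us.
    """
    if k_s < 0:
        raise ValueError("k_s must be >= 0")
    p_s = singlet_projector()
    ident = np.eye(DIM)
    mat = -0.5j * k_s * (np.kron(ident, p_s) + np.kron(p_s.T, ident))
    return Superoperator(matrix=mat, kind="reaction")


def effective_hamiltonian(h: np.ndarray, k_s: float) -> np.ndarray:
    """H_eff = H - i k_s/2 P_S; rho(t) = e^{-i H_eff t} rho e^{+i H_eff^dag t}."""
    return np.asarray(h, dtype=complex) - 0.5j * k_s * singlet_projector()


def free_propagate(
    rho: np.ndarray, h: np.ndarray, duration: float, k_s: float = 0.0
) -> np.ndarray:
    """Field-free evolution of a density matrix, exact to machine precision.

    Uses the two-sided (non-unitary when ``k_s > 0``) matrix exponential of
    the effective Hamiltonian; ``duration`` in us, ``h`` in rad/us.
    """
    if not np.isfinite(duration):
        raise ValueError("duration must be finite")
    if duration == 0.0:
        return np.array(rho, dtype=complex)
    u = scipy.linalg.expm(-1j * effective_hamiltonian(h, k_s) * duration)
    return u @ rho @ u.conj().T


class FreePropagator:
    """Reusable exact propagator for many times of the same Hamiltonian."""

    def __init__(self, h: np.ndarray, k_s: float = 0.0):
        h_eff = effective_hamiltonian(h, k_s)
        if k_s == 0.0:
            self._w, self._v = np.linalg.eigh(h_eff.real if
                                             np.allclose(h_eff.imag, 0) else h_eff)
            self._vinv = self._v.conj().T
        else:
            w, v = scipy.linalg.eig(h_eff)
            self._w, self._v = w, v
            self._vinv = np.linalg.inv(v)

    def at(self, rho: np.ndarray, t: float) -> np.ndarray:
        phases = np.exp(-1j * self._w * t)
        u = (self._v * phases) @ self._vinv
        return u @ rho @ u.conj().T

    def trajectory(
        self, rho: np.ndarray, times: np.ndarray
    ) -> np.ndarray:
        """Stack of rho(t) for each requested time (n_t, 8, 8)."""
        out = np.empty((len(times), DIM, DIM), dtype=complex)
        for i, t in enumerate(times):
            out[i] = self.at(rho, t)
        return out


def check_physical(rho: np.ndarray, reacting: bool, atol: float = 1e-6) -> None:
    """Loud guard against integrator blow-up of the nonlinear dynamics."""
    tr = np.trace(rho).real
    if tr > 1.0 + atol or tr < -atol:
        raise PhysicalityError(f"trace {tr:.6g} outside [0, 1]")
    if not reacting and abs(tr - 1.0) > atol:
        raise PhysicalityError(f"trace {tr:.6g} drifted from 1 without reaction")
    if np.max(np.abs(rho - rho.conj().T)) > 1e-2 * atol + 1e-8:
        raise PhysicalityError("state lost Hermiticity")
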