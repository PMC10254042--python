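"""Target construction for both control modes.

Sub-ensemble control uses static rank-2 projectors onto the two
Hamiltonian eigenstates with the largest T+alpha / T-beta character.
Coherent control uses a moving target: a weighted combination of
operator-valued components back-propagated under the field-free
Liouvillian so that it free-evolves into the desired combination at the
target time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .liouville import vectorize
from .spin_core import (
    BASIS_LABELS,
    DIM,
    RadicalPairSystem,
    hamiltonian,
    projector,
    singlet_projector,
    state_vector,
)


def fix_phase(vec: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude component real-positive (reproducible sign)."""
    idx = int(np.argmax(np.abs(vec)))
    phase = vec[idx] / abs(vec[idx])
    return vec / phase


@dataclass(frozen=True)
class AnisotropicTarget:
    """Rank-2 projector onto the long-lived eigenstate pair of one orientation."""

    orientation_index: int
    projector: np.ndarray
    eigenstate_indices: tuple[int, int]
    overlap_t_plus_alpha: float
    overlap_t_minus_beta: float


def build_anisotropic_target(
    system: RadicalPairSystem, orientation_index: int = 0
) -> AnisotropicTarget:
    """Select the eigenstates maximizing T+alpha and T-beta overlap.

    The target is the sum of the two eigenprojectors; populating it parks
    the pair in states with no singlet character, shutting off the
    singlet recombination channel.
    """
    h = hamiltonian(system)
    _, vecs = np.linalg.eigh(h)
    i_tpa = BASIS_LABELS.index("T+a")
    i_tmb = BASIS_LABELS.index("T-b")
    w_tpa = np.abs(vecs[i_tpa, :]) ** 2
    w_tmb = np.abs(vecs[i_tmb, :]) ** 2
    k_tpa = int(np.argmax(w_tpa))
    k_tmb = int(np.argmax(w_tmb))
    if k_tpa == k_tmb:
        raise ValueError(
            "degenerate target selection: one eigenstate maximizes both "
            "T+alpha and T-beta overlaps"
        )
    pair = [fix_phase(vecs[:, k_tpa]), fix_phase(vecs[:, k_tmb])]
    return AnisotropicTarget(
        orientation_index=orientation_index,
        projector=projector(pair),
        eigenstate_indices=(k_tpa, k_tmb),
        overlap_t_plus_alpha=float(w_tpa[k_tpa]),
        overlap_t_minus_beta=float(w_tmb[k_tmb]),
    )


def performance_index(
    states: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    weights: Sequence[float],
) -> float:
    """y = sum_k q_kj <P_k|rho_k>, linear in every state."""
    if not (len(states) == len(targets) == len(weights)):
        raise ValueError("states, targets and weights must have equal length")
    y = 0.0
    for rho, p, q in zip(states, targets, weights):
        y += q * np.einsum("ij,ij->", np.asarray(p).conj(), np.asarray(rho)).real
    return float(y)


# named operator-valued target components for coherent control; all are
# trace-2 projectors so the q weights carry the same scale in every schedule
_COMPONENTS = {
    "S": lambda: singlet_projector(),
    "T+-": lambda: projector(
        [state_vector("T+a"), state_vector("T+b"),
         state_vector("T-a"), state_vector("T-b")]
    ) / 2.0,
    "T0": lambda: projector([state_vector("T0a"), state_vector("T0b")]),
    "T+a,T-b": lambda: projector([state_vector("T+a"), state_vector("T-b")]),
    "T+b,T-a": lambda: projector([state_vector("T+b"), state_vector("T-a")]),
}


def component_operator(label: str) -> np.ndarray:
    """Operator for a named target component (populations, not kets)."""
    try:
        return _COMPONENTS[label]()
    except KeyError as exc:
        raise ValueError(
            f"unknown component {label!r}; known: {sorted(_COMPONENTS)}"
        ) from exc


class MovingTarget:
    """Back-propagated weighted target, rho_f(t) = e^{+iL0(tf-t)} sum_c q_c |c>.

    Querying at t returns the state that free-evolves into the static
    weighted combination exactly at ``t_f``.
    """

    def __init__(
        self,
        components: Sequence[tuple[float, np.ndarray | str]],
        t_f: float,
        h0: np.ndarray,
    ):
        self.t_f = float(t_f)
        m = np.zeros((DIM, DIM), dtype=complex)
        self.components = []
        for q, comp in components:
            op = component_operator(comp) if isinstance(comp, str) else np.asarray(comp)
            self.components.append((float(q), op))
            m = m + q * op
        self._m_final = m
        self._w, self._v = np.linalg.eigh(np.asarray(h0))
        self._vinv = self._v.conj().T

    @property
    def final_operator(self) -> np.ndarray:
        """The static weighted combination reached at t = t_f."""
        return self._m_final.copy()

    def operator_at(self, t: float) -> np.ndarray:
        if t > self.t_f + 1e-12:
            raise ValueError(f"moving target queried at t={t} > t_f={self.t_f}")
        tau = self.t_f - t
        u = (self._v * np.exp(1j * self._w * tau)) @ self._vinv
        return u @ self._m_final @ u.conj().T

    def query(self, t: float) -> np.ndarray:
        """Vectorized moving target |rho_f(t)>."""
        return vectorize(self.operator_at(t))
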