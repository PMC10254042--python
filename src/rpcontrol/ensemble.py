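"""Euler-angle orientation grids, band weighting and powder averaging.

The default grid samples the polar angle beta only (alpha = gamma = 0):
for an axially symmetric hyperfine tensor the lab-frame Hamiltonian
depends on beta alone.  Jacobian weights carry the |sin beta| measure and
are normalized to unit sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np


@dataclass
class OrientationGrid:
    """A set of Euler-angle cells with Jacobian and control weights."""

    angles: np.ndarray  # (n_cells, 3) Euler angles in radians
    jacobian: np.ndarray  # normalized |sin beta| weights, sum 1
    control_q: np.ndarray  # per-cell weighting factor q_k

    @property
    def n_cells(self) -> int:
        return len(self.angles)

    @property
    def beta_deg(self) -> np.ndarray:
        return np.degrees(self.angles[:, 1])

    @property
    def control_weights(self) -> np.ndarray:
        """q_kj = q_k * normalized |sin beta| Jacobian."""
        return self.control_q * self.jacobian


def build_grid(
    beta_step_deg: float = 10.0,
    alpha_values_deg: Sequence[float] = (0.0,),
    gamma_values_deg: Sequence[float] = (0.0,),
) -> OrientationGrid:
    """Uniform beta grid over [0, 180] degrees, optionally crossed with
    alpha/gamma samples for non-axial tensors."""
    n_beta = 180.0 / beta_step_deg
    if abs(n_beta - round(n_beta)) > 1e-9:
        raise ValueError("beta_step_deg must divide 180")
    betas = np.linspace(0.0, 180.0, int(round(n_beta)) + 1)
    cells = []
    for a in alpha_values_deg:
        for b in betas:
            for g in gamma_values_deg:
                cells.append((a, b, g))
    angles = np.radians(np.array(cells))
    jac = np.abs(np.sin(angles[:, 1]))
    total = jac.sum()
    if total <= 0:
        raise ValueError("zero-measure orientation grid")
    return OrientationGrid(
        angles=angles,
        jacobian=jac / total,
        control_q=np.ones(len(angles)),
    )


def _parse_band(key: str) -> tuple[float, float]:
    lo, hi = key.split("-")
    return float(lo), float(hi)


def assign_band_weights(
    grid: OrientationGrid, bands: Mapping[str, float]
) -> OrientationGrid:
    """Attach control weights q per beta band, e.g. ``{"0-50": 5, "60-120": -3}``.

    Cells in unlisted gaps get q = 0 (neither driven nor penalized).
    Band edges are inclusive; overlapping bands are rejected.
    """
    ranges = sorted((_parse_band(k), float(q)) for k, q in bands.items())
    for (r1, _), (r2, _) in zip(ranges, ranges[1:]):
        if r2[0] < r1[1]:
            raise ValueError(f"overlapping beta bands {r1} and {r2}")
    beta = grid.beta_deg
    q = np.zeros(grid.n_cells)
    for (lo, hi), val in ranges:
        mask = (beta >= lo - 1e-9) & (beta <= hi + 1e-9)
        q[mask] = val
    return OrientationGrid(
        angles=grid.angles.copy(), jacobian=grid.jacobian.copy(), control_q=q
    )


def powder_average(
    series: np.ndarray, grid: OrientationGrid,
    bands: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Jacobian-weighted orientation average of per-cell time series.

    ``series`` has shape (n_cells, n_times).  Returns the full average
    under key ``"all"`` plus one renormalized average per requested beta
    band (for band-resolved decay reporting).
    """
    series = np.asarray(series)
    if series.shape[0] != grid.n_cells:
        raise ValueError(
            f"series has {series.shape[0]} cells, grid has {grid.n_cells}"
        )
    out = {"all": grid.jacobian @ series}
    if bands:
        beta = grid.beta_deg
        for key in bands:
            lo, hi = _parse_band(key)
            mask = (beta >= lo - 1e-9) & (beta <= hi + 1e-9)
            w = grid.jacobian * mask
            total = w.sum()
            if total > 0:
                out[key] = (w / total) @ series
    return out
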