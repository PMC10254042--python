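"""Bounded derivative-free search over the control meta-parameters.

A small real-coded genetic algorithm (tournament selection, blend
crossover, Gaussian mutation, one elite) maximizes the final-state
fidelity f(q_i, A) = <f|rho(t_f)> returned by one local-optimization
run per parameter set.  Whole generations are evaluated in a single
vectorized integration.  A seeded random search is provided as an
independent baseline oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SearchSpec", "GenerationRecord", "ga_search", "random_search"]


@dataclass(frozen=True)
class SearchSpec:
    """Bounds and budget for the parameter search.

    ``bounds`` maps parameter name -> (low, high); the default ranges are
    the published search box for {q_intermediate, q_S, A/mT}.
    """

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "q_intermediate": (0.5, 0.9),
            "q_final": (0.9, 1.5),
            "amplitude": (0.1, 3.0),
        }
    )
    population: int = 50
    generations: int = 50
    seed: int = 0
    tournament: int = 3
    blend_alpha: float = 0.5
    mutation_sigma_frac: float = 0.05
    mutation_prob: float = 0.2
    elite: int = 1

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def lows_highs(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([b[0] for b in self.bounds.values()])
        hi = np.array([b[1] for b in self.bounds.values()])
        return lo, hi


@dataclass
class GenerationRecord:
    generation: int
    f_max: float
    f_min: float
    best_params: dict[str, float]


def _evaluate(
    objective: Callable[[np.ndarray], np.ndarray], pop: np.ndarray
) -> np.ndarray:
    """Batch-evaluate; a failed batch degrades to per-row with 0 on error."""
    try:
        return np.asarray(objective(pop), dtype=float)
    except Exception:
        out = np.zeros(len(pop))
        for i, row in enumerate(pop):
            try:
                out[i] = float(np.asarray(objective(row[None]))[0])
            except Exception:
                out[i] = 0.0
        return out


def ga_search(
    spec: SearchSpec,
    objective: Callable[[np.ndarray], np.ndarray],
) -> tuple[dict[str, float], float, list[GenerationRecord]]:
    """Maximize ``objective`` (vectorized over a (n, d) parameter array).

    Returns (best parameter dict, best fidelity, per-generation history).
    Fully deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.lows_highs()
    d = len(lo)
    pop = lo + (hi - lo) * rng.random((spec.population, d))
    fit = _evaluate(objective, pop)
    history: list[GenerationRecord] = []
    best_x, best_f = pop[np.argmax(fit)].copy(), float(np.max(fit))

    def record(gen: int) -> None:
        history.append(
            GenerationRecord(
                generation=gen,
                f_max=float(np.max(fit)),
                f_min=float(np.min(fit)),
                best_params=dict(zip(spec.names, pop[np.argmax(fit)])),
            )
        )

    record(0)
    for gen in range(1, spec.generations + 1):
        order = np.argsort(fit)[::-1]
        elite = pop[order[: spec.elite]].copy()
        children = []
        while len(children) < spec.population - spec.elite:
            # tournament selection of two parents
            idx = rng.integers(0, spec.population, (2, spec.tournament))
            parents = pop[[c[np.argmax(fit[c])] for c in idx]]
            # blend (BLX-alpha) crossover
            span = np.abs(parents[1] - parents[0])
            c_lo = np.minimum(parents[0], parents[1]) - spec.blend_alpha * span
            c_hi = np.maximum(parents[0], parents[1]) + spec.blend_alpha * span
            child = c_lo + (c_hi - c_lo) * rng.random(d)
            # Gaussian mutation
            mutate = rng.random(d) < spec.mutation_prob
            child = child + mutate * rng.normal(0.0, spec.mutation_sigma_frac * (hi - lo))
            children.append(np.clip(child, lo, hi))
        pop = np.vstack([elite, np.array(children)])
        fit = np.concatenate(
            [fit[order[: spec.elite]], _evaluate(objective, np.array(children))]
        )
        if np.max(fit) > best_f:
            best_f = float(np.max(fit))
            best_x = pop[np.argmax(fit)].copy()
        record(gen)
    return dict(zip(spec.names, best_x)), best_f, history


def random_search(
    spec: SearchSpec,
    objective: Callable[[np.ndarray], np.ndarray],
    n_points: int = 200,
) -> tuple[dict[str, float], float]:
    """Uniform random baseline over the same bounds (independent oracle)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.lows_highs()
    pts = lo + (hi - lo) * rng.random((n_points, len(lo)))
    vals = _evaluate(objective, pts)
    i = int(np.argmax(vals))
    return dict(zip(spec.names, pts[i])), float(vals[i])
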