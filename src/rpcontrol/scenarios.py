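"""Packaged model scenarios, config I/O, fixtures and high-level runners.

Config keys carry explicit units (``b0_mT``, ``j_MHz``, ``k_s_per_s``)
because unit mixing between mT and MHz is the most likely user error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from .ensemble import assign_band_weights, build_grid, powder_average
from .liouville import FreePropagator
from .optimizer import (
    ControlConfig,
    ControlResult,
    optimize_coherent,
    optimize_coherent_batch,
    optimize_ensemble,
)
from .search import SearchSpec, ga_search
from .spin_core import (
    RadicalPairSystem,
    control_operator,
    hamiltonian,
    initial_singlet_state,
    singlet_projector,
)
from .targets import MovingTarget, build_anisotropic_target

BUILTIN_NAMES = [
    "iso-keep-3.6mT",
    "aniso-parallel-3.6mT",
    "aniso-perpendicular-3.6mT",
    "coherent-20mT",
    "coherent-0.05mT",
]


@dataclass
class Scenario:
    """A fully declared control problem (system + targets + settings)."""

    name: str
    mode: str  # "ensemble" | "coherent"
    system: dict[str, Any]
    control: dict[str, Any]
    ensemble: dict[str, Any] = field(default_factory=dict)
    coherent: dict[str, Any] = field(default_factory=dict)
    search: dict[str, Any] = field(default_factory=dict)
    description: str = ""

    def to_dict(self) -> dict[str, Any]:
        return {
            "name": self.name,
            "description": self.description,
            "mode": self.mode,
            "system": self.system,
            "control": self.control,
            "ensemble": self.ensemble or None,
            "coherent": self.coherent or None,
            "search": self.search or None,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Scenario":
        if data.get("mode") not in ("ensemble", "coherent"):
            raise ValueError(f"mode must be ensemble or coherent, got {data.get('mode')!r}")
        return cls(
            name=str(data["name"]),
            description=str(data.get("description", "")),
            mode=str(data["mode"]),
            system=dict(data["system"]),
            control=dict(data["control"]),
            ensemble=dict(data.get("ensemble") or {}),
            coherent=dict(data.get("coherent") or {}),
            search=dict(data.get("search") or {}),
        )

    # -- physics builders ------------------------------------------------
    def radical_pair(self, euler=(0.0, 0.0, 0.0)) -> RadicalPairSystem:
        s = self.system
        hf = s.get("hyperfine_mT")
        return RadicalPairSystem(
            g_a=float(s.get("g_a", 2.000)),
            g_b=float(s.get("g_b", 2.002)),
            b0=float(s.get("b0_mT", 0.0)),
            hyperfine_principal=tuple(hf) if hf else (0.0, 0.0, 0.0),
            a_iso_MHz=(float(s["a_iso_MHz"]) if "a_iso_MHz" in s
                       and s["a_iso_MHz"] is not None else None),
            j_exchange=float(s.get("j_MHz", 0.0)),
            k_s=float(s.get("k_s_per_s", 0.0)) * 1e-6,  # 1/s -> 1/us
            euler=tuple(float(x) for x in euler),
        )

    def control_config(self, **overrides: Any) -> ControlConfig:
        c = dict(self.control)
        c.update(overrides)
        return ControlConfig(
            amplitude=float(c["amplitude_mT"]),
            t_f=float(c["t_f_us"]),
            output_step_ns=float(c.get("output_step_ns", 0.25)),
            mode=self.mode,
            rtol=float(c.get("rtol", 1e-8)),
            atol=float(c.get("atol", 1e-10)),
            seed_kick=float(c.get("seed_kick_rad", 0.01)),
        )

    def moving_target(self, t_f: float | None = None) -> MovingTarget:
        if self.mode != "coherent":
            raise ValueError("moving_target only defined for coherent scenarios")
        h0 = hamiltonian(self.radical_pair())
        comps = [(float(c["q"]), str(c["state"]))
                 for c in self.coherent["components"]]
        if t_f is None:
            t_f = float(self.control["t_f_us"])
        return MovingTarget(comps, t_f, h0)

    def search_spec(self, **overrides: Any) -> SearchSpec:
        s = dict(self.search)
        s.update(overrides)
        bounds = {k: tuple(v) for k, v in s.get(
            "bounds",
            {"q_intermediate": (0.5, 0.9), "q_final": (0.9, 1.5),
             "amplitude": (0.1, 3.0)},
        ).items()}
        return SearchSpec(
            bounds=bounds,
            population=int(s.get("population", 50)),
            generations=int(s.get("generations", 50)),
            seed=int(s.get("seed", 0)),
        )

    # -- persistence -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def list_scenarios() -> list[str]:
    return list(BUILTIN_NAMES)


def load_scenario(name_or_path: str | Path) -> Scenario:
    """Load a built-in scenario by name or any scenario YAML by path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        data = yaml.safe_load(path.read_text())
    else:
        if str(name_or_path) not in BUILTIN_NAMES:
            raise KeyError(
                f"unknown scenario {name_or_path!r}; built-ins: {BUILTIN_NAMES}"
            )
        ref = resources.files("rpcontrol") / "scenarios" / f"{name_or_path}.yaml"
        data = yaml.safe_load(ref.read_text())
    return Scenario.from_dict(data)


def make_fixture(kind: str) -> Scenario:
    """Degenerate toy systems with closed-form dynamics for oracle tests."""
    base_control = {"amplitude_mT": 1.0, "t_f_us": 1.0, "output_step_ns": 1.0}
    if kind == "no-hyperfine":
        # equal g, no hyperfine: the singlet is stationary for any J
        return Scenario(
            name="fixture-no-hyperfine", mode="coherent",
            system={"g_a": 2.0, "g_b": 2.0, "b0_mT": 1.0, "j_MHz": 0.5},
            control=base_control,
            coherent={"components": [{"state": "S", "q": 1.0}]},
        )
    if kind == "equal-g":
        # S-T0 oscillation driven purely by the isotropic hyperfine coupling
        return Scenario(
            name="fixture-equal-g", mode="coherent",
            system={"g_a": 2.0, "g_b": 2.0, "b0_mT": 20.0, "a_iso_MHz": 15.0,
                    "j_MHz": 0.0},
            control=base_control,
            coherent={"components": [{"state": "S", "q": 1.0}]},
        )
    if kind == "two-level-reduction":
        # no hyperfine, exaggerated delta-g: drive S <-> T+/- via the
        # antisymmetric part of the control operator; Rabi-like transfer
        # saturating at y = 1/2 (equal branching into T+ and T-)
        return Scenario(
            name="fixture-two-level", mode="ensemble",
            system={"g_a": 2.000, "g_b": 2.2, "b0_mT": 3.6, "j_MHz": 0.0},
            control={"amplitude_mT": 3.0, "t_f_us": 2.0, "output_step_ns": 0.5},
        )
    raise ValueError(f"unknown fixture kind {kind!r}")


# ---------------------------------------------------------------------------
# high-level runners


def run_scenario(
    scenario: Scenario, out_dir: str | Path | None = None, **config_overrides: Any
) -> dict[str, Any]:
    """Execute one scenario end to end; optionally write CSV/JSON outputs.

    Returns a dict with the ``ControlResult`` under ``"result"`` and a
    JSON-serializable ``"summary"``.
    """
    config = scenario.control_config(**config_overrides)
    rho0 = initial_singlet_state()
    if scenario.mode == "ensemble":
        out = _run_ensemble(scenario, config, rho0)
    else:
        out = _run_coherent(scenario, config, rho0)
    out["summary"]["scenario"] = scenario.name
    out["summary"]["config_hash"] = scenario.config_hash()
    if out_dir is not None:
        _write_outputs(Path(out_dir), scenario, out)
    return out


def _run_ensemble(
    scenario: Scenario, config: ControlConfig, rho0: np.ndarray
) -> dict[str, Any]:
    ens = scenario.ensemble
    grid = build_grid(float(ens.get("beta_step_deg", 10.0)))
    bands = ens.get("bands")
    if bands:
        grid = assign_band_weights(grid, bands)
    systems = [scenario.radical_pair(ang) for ang in grid.angles]
    hams = [hamiltonian(s) for s in systems]
    targets = [build_anisotropic_target(s, k).projector
               for k, s in enumerate(systems)]
    k_s = systems[0].k_s
    result = optimize_ensemble(
        hams, control_operator(systems[0]), targets, grid.control_weights,
        rho0, config, k_s=k_s,
    )
    averages = powder_average(result.populations["trace"], grid, bands)
    # free-decay reference on the same grid (exact propagation)
    free_tr = np.empty(grid.n_cells)
    for k, h in enumerate(hams):
        free_tr[k] = np.trace(
            FreePropagator(h, k_s=k_s).at(rho0, config.t_f)
        ).real
    i_quarter = min(int(np.searchsorted(result.times, 0.25)),
                    len(result.times) - 1)
    summary = {
        "mode": "ensemble",
        "averaged_trace_final": float(averages["all"][-1]),
        "averaged_trace_final_no_rf": float(grid.jacobian @ free_tr),
        "band_averages_final": {k: float(v[-1]) for k, v in averages.items()},
        "y_final": float(result.y[-1]),
        "y_ratio_quarter_us": float(result.y[i_quarter] / result.y[-1]),
        "max_field_mT": float(np.max(np.abs(result.u))),
        "t_f_us": config.t_f,
    }
    return {"result": result, "summary": summary, "grid": grid,
            "averages": averages}


def _run_coherent(
    scenario: Scenario, config: ControlConfig, rho0: np.ndarray
) -> dict[str, Any]:
    system = scenario.radical_pair()
    h0 = hamiltonian(system)
    result = optimize_coherent(
        h0, control_operator(system), scenario.moving_target(config.t_f),
        rho0, config,
    )
    # free-evolution singlet probability at t_f, exact reference
    rho_free = FreePropagator(h0).at(rho0, config.t_f)
    p_free = float(np.trace(singlet_projector() @ rho_free).real)
    summary = {
        "mode": "coherent",
        "final_fidelity": float(result.final_fidelity),
        "free_evolution_fidelity": p_free,
        "y_final": float(result.y[-1]),
        "max_field_mT": float(np.max(np.abs(result.u))),
        "t_f_us": config.t_f,
    }
    return {"result": result, "summary": summary}


def search_scenario(
    scenario: Scenario,
    population: int | None = None,
    generations: int | None = None,
    seed: int | None = None,
) -> dict[str, Any]:
    """Global search of {q_intermediate, q_final, A} for a coherent scenario."""
    if scenario.mode != "coherent":
        raise ValueError("parameter search applies to coherent scenarios")
    overrides = {}
    if population is not None:
        overrides["population"] = population
    if generations is not None:
        overrides["generations"] = generations
    if seed is not None:
        overrides["seed"] = seed
    spec = scenario.search_spec(**overrides)
    system = scenario.radical_pair()
    h0 = hamiltonian(system)
    v = control_operator(system)
    rho0 = initial_singlet_state()
    config = scenario.control_config()
    comps = scenario.coherent["components"]
    if len(comps) != 2:
        raise ValueError("search expects exactly two target components")
    intermediate_state = str(comps[0]["state"])
    final_state = str(comps[1]["state"])

    def objective(pop: np.ndarray) -> np.ndarray:
        pop = np.atleast_2d(pop)
        mts = [
            MovingTarget(
                [(qi, intermediate_state), (qf, final_state)], config.t_f, h0
            )
            for qi, qf, _ in pop
        ]
        return optimize_coherent_batch(h0, v, mts, pop[:, 2], rho0, config)

    best, best_f, history = ga_search(spec, objective)
    return {
        "best_params": best,
        "best_fidelity": best_f,
        "history": [
            {"generation": h.generation, "f_max": h.f_max, "f_min": h.f_min,
             **{f"best_{k}": v for k, v in h.best_params.items()}}
            for h in history
        ],
        "spec": {"population": spec.population,
                 "generations": spec.generations, "seed": spec.seed},
    }


def _write_outputs(out_dir: Path, scenario: Scenario, out: dict[str, Any]) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    result: ControlResult = out["result"]
    pd.DataFrame(
        {"t_ns": result.times * 1e3, "u_mT": result.u}
    ).to_csv(out_dir / "waveform.csv", index=False)
    traj = {"t_us": result.times, "y": result.y}
    for name, arr in result.populations.items():
        if arr.shape[0] == 1:
            traj[name] = arr[0]
        else:
            for k in range(arr.shape[0]):
                traj[f"{name}_k{k}"] = arr[k]
    pd.DataFrame(traj).to_csv(out_dir / "trajectories.csv", index=False)
    (out_dir / "summary.json").write_text(
        json.dumps(out["summary"], indent=2, sort_keys=True)
    )
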