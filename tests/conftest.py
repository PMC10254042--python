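import numpy as np
import pytest

from rpcontrol.ensemble import build_grid
from rpcontrol.spin_core import (
    RadicalPairSystem,
    control_operator,
    hamiltonian,
    initial_singlet_state,
)


@pytest.fixture(scope="session")
def powder_system() -> RadicalPairSystem:
    """The anisotropic 3.6 mT reference system (one orientation template)."""
    return RadicalPairSystem(
        g_a=2.000, g_b=2.002, b0=3.6,
        hyperfine_principal=(1.2, 1.2, 1.8), j_exchange=0.1, k_s=1.0,
    )


@pytest.fixture(scope="session")
def lowfield_system() -> RadicalPairSystem:
    return RadicalPairSystem(
        g_a=2.000, g_b=2.000, b0=0.05, a_iso_MHz=15.0, j_exchange=0.1
    )


@pytest.fixture(scope="session")
def highfield_system() -> RadicalPairSystem:
    return RadicalPairSystem(
        g_a=2.000, g_b=2.000, b0=20.0, a_iso_MHz=15.0, j_exchange=0.1
    )


@pytest.fixture(scope="session")
def beta_grid():
    return build_grid(10.0)


@pytest.fixture(scope="session")
def rho0() -> np.ndarray:
    return initial_singlet_state()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_density_matrix(rng: np.random.Generator, dim: int = 8) -> np.ndarray:
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    rho = a @ a.conj().T
    return rho / np.trace(rho)


def random_hermitian(rng: np.random.Generator, dim: int = 8,
                     scale: float = 1.0) -> np.ndarray:
    a = rng.normal(size=(dim, dim)) + 1j * rng.normal(size=(dim, dim))
    return scale * (a + a.conj().T) / 2.0
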