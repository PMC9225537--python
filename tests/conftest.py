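import numpy as np
import pytest

from melamet import (
    DEFAULT_GRID,
    build_basis,
    load_standard_cmfs,
    load_standard_observer,
    synthetic_observer,
)


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID


@pytest.fixture(scope="session")
def std_observer(grid):
    return load_standard_observer(grid)


@pytest.fixture(scope="session")
def std_basis(std_observer):
    return build_basis(std_observer)


@pytest.fixture(scope="session")
def std_cmfs(grid):
    return load_standard_cmfs(grid)


@pytest.fixture(scope="session")
def disjoint_observer(grid):
    """Five sensitivities with disjoint supports: orthogonal by construction."""
    from melamet.core import SensitivityFunction
    from melamet.observers import PhotoreceptorSet

    lam = grid.wavelengths
    base = synthetic_observer(5, [420, 480, 540, 600, 680], [0.02] * 5, grid=grid)
    sens = []
    for row, center in zip(base.as_matrix(), [420, 480, 540, 600, 680]):
        v = np.where(np.abs(lam - center) <= 25, row, 0.0)
        sens.append(SensitivityFunction(grid, v / v.max(), name=f"d{center}"))
    return PhotoreceptorSet(tuple(sens), provenance="disjoint synthetic")


def random_feasible_targets(obs, rng):
    """Cone+rod excitation targets realized by an actual bounded spectrum."""
    from melamet import Spectrum, excitations_percent

    p = Spectrum(obs.grid, rng.uniform(5.0, 95.0, obs.grid.n_samples))
    return excitations_percent(p, obs).as_array()[: len(obs) - 1]
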