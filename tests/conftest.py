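import numpy as np
import pytest

from raftedge import Grid, MembraneParameters, RegionLayout, membrane


@pytest.fixture(scope="session")
def default_membrane() -> MembraneParameters:
    return membrane("default")


@pytest.fixture(scope="session")
def coarse_grid() -> Grid:
    """Fast settings for tests: still within ~0.5% of converged energies."""
    return Grid(dx=0.05, half_width=15.0)


@pytest.fixture(scope="session")
def tiny_grid() -> Grid:
    """Very small box for brute-force cross-check problems."""
    return Grid(dx=0.05, half_width=3.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


def random_smooth_field(layout: RegionLayout, x: np.ndarray,
                        rng: np.random.Generator, amplitude: float = 0.05):
    """A random admissible deformation: flat state + smooth decaying bumps."""
    from raftedge import DeformationField

    field = DeformationField.flat(x, layout)
    envelope = np.exp(-((x - x.mean()) / (0.25 * (x[-1] - x[0]))) ** 2)
    for name in ("n_u", "n_l", "H_u", "H_l", "M"):
        arr = getattr(field, name)
        k = rng.uniform(0.3, 1.5, size=3)
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0, amplitude, size=3)
        bump = sum(a * np.cos(kk * x + p) for a, kk, p in zip(amp, k, phase))
        setattr(field, name, arr + bump * envelope)
    return field
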