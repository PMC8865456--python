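import numpy as np
import pytest
from scipy import stats

from klsenet.atlas import ParcellationAtlas
from klsenet.density import DEFAULT_GRID, DensityEstimate, StandardGrid
from klsenet.synthetic import PhantomSpec, build_phantom_atlas


def gaussian_estimate(mu, sd, grid: StandardGrid = DEFAULT_GRID, parcel_id: int = 1) -> DensityEstimate:
    """Analytic normal PDF discretized on a grid (trapezoid-renormalized)."""
    dens = stats.norm.pdf(grid.points, mu, sd)
    dens = dens / np.trapezoid(dens, dx=grid.spacing)
    return DensityEstimate(parcel_id, grid, dens, float(sd))


def random_weight_matrix(rng: np.random.Generator, n: int, low: float = 0.2, high: float = 1.0) -> np.ndarray:
    """Symmetric complete weighted graph with unit diagonal."""
    w = rng.uniform(low, high, (n, n))
    w = (w + w.T) / 2.0
    np.fill_diagonal(w, 1.0)
    return w


@pytest.fixture(scope="session")
def default_atlas() -> ParcellationAtlas:
    return build_phantom_atlas()


@pytest.fixture(scope="session")
def small_atlas() -> ParcellationAtlas:
    """Small phantom: 20 parcels x 60 voxels in 4 networks (fast tests)."""
    spec = PhantomSpec(
        volume_shape=(12, 10, 11),
        parcel_voxel_count=60,
        network_sizes={"net_a": 6, "net_b": 5, "net_c": 5, "net_d": 4},
        min_voxels=60,
        seed=42,
    )
    return build_phantom_atlas(spec)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(
        volume_shape=(12, 10, 11),
        parcel_voxel_count=60,
        network_sizes={"net_a": 6, "net_b": 5, "net_c": 5, "net_d": 4},
        min_voxels=60,
        seed=42,
    )
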