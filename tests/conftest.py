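import numpy as np
import pytest

from boundarydose.dvh import DoseGrid, StructureMask


@pytest.fixture
def rng():
    return np.random.default_rng(20250905)


def make_grid(values, spacing=(2.5, 2.5, 2.5)):
    return DoseGrid(values=np.asarray(values, dtype=float), spacing=spacing)


def make_mask(values, name="mask"):
    return StructureMask(name=name, values=np.asarray(values, dtype=bool))


@pytest.fixture
def uniform_40() -> tuple[DoseGrid, StructureMask]:
    """A 10-voxel structure receiving a uniform 40 Gy."""
    values = np.zeros((2, 3, 4))
    mask = np.zeros((2, 3, 4), dtype=bool)
    mask.flat[:10] = True
    values[mask] = 40.0
    return make_grid(values), make_mask(mask, "uniform10")


def random_case(rng, shape=(5, 6, 7), max_dose=55.0):
    """Random dose grid plus a random non-empty mask on the same lattice."""
    values = rng.uniform(0.0, max_dose, size=shape)
    mask = rng.random(shape) < 0.4
    if not mask.any():
        mask.flat[rng.integers(mask.size)] = True
    return make_grid(values), make_mask(mask)


@pytest.fixture
def small_cohort_sims():
    """Three tiny simulated patients (module-scope speed helper)."""
    from boundarydose.synthetic import CohortConfig, simulate_cohort

    config = CohortConfig(
        n_patients=3, ptv_volume_range_cc=(15.4, 60.0), seed=11
    )
    return simulate_cohort(config)
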