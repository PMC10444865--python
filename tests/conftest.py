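import numpy as np
import pytest

from cspws import dmap
from cspws.instrument import GridSpec, make_default_instrument


@pytest.fixture(scope="session")
def instrument():
    return make_default_instrument()


@pytest.fixture(scope="session")
def kernel(instrument):
    return dmap.smoothing_kernel(instrument)


@pytest.fixture(scope="session")
def acf_template():
    return dmap.AcfModel(d_b=2.0)


@pytest.fixture(scope="session")
def lookup(acf_template, kernel, instrument):
    """Default Sigma(D_b) lookup table; built once per session (~10 s)."""
    return dmap.build_sigma_db_lookup(acf_template, kernel, instrument)


@pytest.fixture(scope="session")
def small_grid():
    """Single-cell synthesis grid sized for fast tests (transverse 1.4 um)."""
    return GridSpec(nx=128, ny=128, nz=448, voxel_nm=11.0)


def simulate_cell_sigma(model, grid, instrument, seed):
    """End-to-end: density field -> RI -> cube -> normalized -> Sigma image."""
    from cspws.instrument import (
        compute_sigma_image,
        density_to_ri,
        interior_mask,
        make_reference_cube,
        reference_normalize,
        sample_chromatin_density,
        simulate_interference_cube,
    )

    realization = sample_chromatin_density(model, grid, seed)
    ri = density_to_ri(realization, instrument)
    cube = simulate_interference_cube(ri, grid, instrument)
    ref = make_reference_cube(instrument, cube.values.shape[:2])
    norm = reference_normalize(cube, ref)
    mask = interior_mask(norm.values.shape[:2], 0.1)
    return compute_sigma_image(norm, mask)
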