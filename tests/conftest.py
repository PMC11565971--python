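import numpy as np
import pytest

from thalamap import ChainParams, gen_brain_from_atlas, gen_mini_atlas


@pytest.fixture(scope="session")
def mini_atlas():
    return gen_mini_atlas(n_regions=6, seed=11)


@pytest.fixture(scope="session")
def small_atlas():
    """A coarse atlas small enough for exhaustive voxel-scan oracles."""
    return gen_mini_atlas(n_regions=3, shape=(30, 22, 21), voxel_um=10.0, seed=7)


@pytest.fixture(scope="session")
def identity_brain(mini_atlas):
    return gen_brain_from_atlas(mini_atlas, n_cells=150, seed=21)


@pytest.fixture(scope="session")
def transformed_brain(mini_atlas):
    params = ChainParams(
        t_ap=900.0, t_dv=-500.0, t_ml=350.0, shear=0.04,
        ap_scale=1.15, dv_scale=0.85, ml_scale=1.10,
    )
    return gen_brain_from_atlas(
        mini_atlas, chain_params=params, n_cells=250, seed=22
    )


def brain_cell_points(brain):
    return np.column_stack(
        [
            brain.cells["section_index"].to_numpy() * brain.section_thickness_um,
            brain.cells["dv_um"].to_numpy(),
            brain.cells["ml_um"].to_numpy(),
        ]
    )
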