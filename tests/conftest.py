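import numpy as np
import pytest

from airtree import phantom as ph
from airtree.decomposition import decompose


@pytest.fixture(scope="session")
def grid128():
    return ph.default_grid()


@pytest.fixture(scope="session")
def tree5_bundle(grid128):
    """Jitter-free 5-generation phantom: tree, airway, truth, lung."""
    tree = ph.generate_tree(ph.TreeSpec(n_generations=5), grid128)
    airway, truth = ph.rasterize_tree(tree)
    lung = ph.generate_lung_mask(grid128, tree)
    return {"tree": tree, "airway": airway, "truth": truth, "lung": lung}


@pytest.fixture(scope="session")
def tree6_bundle(grid128):
    with pytest.warns(UserWarning):
        tree = ph.generate_tree(ph.TreeSpec(n_generations=6), grid128)
        airway, truth = ph.rasterize_tree(tree)
    lung = ph.generate_lung_mask(grid128, tree)
    return {"tree": tree, "airway": airway, "truth": truth, "lung": lung}


@pytest.fixture(scope="session")
def tree5_result(tree5_bundle):
    return decompose(tree5_bundle["airway"], tree5_bundle["lung"])


def make_two_tube_mask(grid, split_slice=20, z_end=60, offset=5, radius=3.0,
                       center=(63.0, 63.0)):
    """One tube above ``split_slice``, two parallel tubes below: a hand-built
    trachea/carina geometry with the split at a known slice."""
    cy, cx = center
    zz = np.arange(grid.shape[0])[:, None, None] * grid.spacing[0]
    yy = np.arange(grid.shape[1])[None, :, None] * grid.spacing[1]
    xx = np.arange(grid.shape[2])[None, None, :] * grid.spacing[2]
    vox = np.zeros(grid.shape, dtype=bool)
    above = (zz[:, 0, 0] < split_slice * grid.spacing[0])
    single = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    vox |= above[:, None, None] & single
    below = (zz[:, 0, 0] >= split_slice * grid.spacing[0]) & (
        zz[:, 0, 0] < z_end * grid.spacing[0]
    )
    pair = ((yy - cy) ** 2 + (xx - (cx - offset)) ** 2 <= radius**2) | (
        (yy - cy) ** 2 + (xx - (cx + offset)) ** 2 <= radius**2
    )
    vox |= below[:, None, None] & pair
    return vox
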