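import warnings

import numpy as np
import pytest

from virtustain.synthetic import CellSpec, SceneSpec, render_scene


@pytest.fixture(scope="session")
def one_cell_scene():
    """Single head with a 3:1 dsDNA:ssDNA intensity ratio (true DFI 25%)."""
    cell = CellSpec(center=(80.0, 80.0), axes=(12.0, 8.0), angle=30.0,
                    dsdna_intensity=75.0, ssdna_intensity=25.0)
    spec = SceneSpec(cells=(cell,), bg_jitter=0)
    return spec, render_scene(spec)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Two-donor on-disk dataset (10 cells each) with random misalignments."""
    from virtustain.synthetic import generate_donor_dataset

    root = tmp_path_factory.mktemp("dataset")
    truth = generate_donor_dataset(root, n_donors=2, cells_per_donor=10, seed=7)
    return root, truth


@pytest.fixture(autouse=True)
def _quiet_degenerate_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*distinct value.*", category=UserWarning
        )
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(42)
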