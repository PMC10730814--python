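import numpy as np
import pytest

from organoid3d.plate_io import PlateLayout
from organoid3d.synthetic_data import SimulationConfig


def small_layout() -> PlateLayout:
    """2x2 fields of 96x96 px, 18 planes, voxel (2,1,1) µm — fast unit-test scale."""
    return PlateLayout(
        rows=2, cols=2, field_grid=(2, 2), planes_per_field=18,
        channels=("egfp", "mcherry", "draq7"), field_shape_px=(96, 96),
        voxel_size_um=(2.0, 1.0, 1.0),
    )


def small_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Three small organoids of ~10 nuclei each; renders in about a second."""
    kw = dict(
        layout=small_layout(),
        n_organoids=3,
        organoid_radius_um=(18.0, 1.0),
        organoid_z_radius_um=(10.0, 1.0),
        organoid_gap_um=12.0,
        nuclei_per_organoid=(10.0, 2.0),
        seed=seed,
    )
    kw.update(overrides)
    return SimulationConfig(**kw)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_well():
    """One rendered small synthetic well + its ground truth (shared, read-only)."""
    from organoid3d.synthetic_data import generate_well_volume

    cfg = small_config(seed=7)
    vol, truth = generate_well_volume(cfg)
    return cfg, vol, truth
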