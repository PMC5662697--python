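import numpy as np
import pytest

import mpradiomics as mp
from mpradiomics.standardization import QuantizedRegion


def region_from_levels(levels: np.ndarray, n_levels: int | None = None) -> QuantizedRegion:
    """Build a QuantizedRegion directly from an integer level array (0 = outside)."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[..., None]
    L = int(n_levels or levels.max())
    mask = levels > 0
    return QuantizedRegion(levels, mask, L, np.arange(1, L + 1, dtype=float))


@pytest.fixture(scope="session")
def small_spec():
    """A compact phantom spec used across tests (tumor fits a 32^3 mm box)."""
    return mp.PhantomSpec(
        n_patients=4,
        volume_shape=(32, 32, 32),
        subregion_radii_mm={"necrosis": 3.5, "enhancing": 6.0,
                            "non_enhancing": 8.5, "edema": 11.0},
        seed=11,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return mp.generate_phantom(small_spec, 0)


@pytest.fixture(scope="session")
def full_grid():
    return mp.enumerate_grid()


@pytest.fixture(scope="session")
def full_feature_row(full_grid):
    """One default-size phantom pushed through the complete 36-setting grid."""
    spec = mp.PhantomSpec(n_patients=2, seed=5)
    study = mp.generate_phantom(spec, 0)
    return mp.extract_study(study, full_grid)
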