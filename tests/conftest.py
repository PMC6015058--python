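import numpy as np
import pytest

from bhts.plate_io import Plate, ScreenDataset, WellRole


def make_plate(values, plate_id="P1", roles=None):
    values = np.asarray(values, dtype=float)
    if roles is None:
        roles = np.empty(values.shape, dtype=object)
        roles[:, :] = WellRole.COMPOUND
    return Plate(plate_id=plate_id, values=values, roles=roles)


def all_compound_dataset(value_matrices, truth=None):
    plates = [make_plate(v, plate_id=f"P{i + 1}") for i, v in enumerate(value_matrices)]
    return ScreenDataset(plates=plates, truth=truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_plate(rng):
    return make_plate(rng.normal(0.2, 0.05, size=(8, 10)))


@pytest.fixture
def small_dataset(rng):
    mats = [rng.normal(0.15, 0.05, size=(4, 5)) for _ in range(3)]
    return all_compound_dataset(mats)
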