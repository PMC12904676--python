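import numpy as np
import pytest

from healthaccess.raster_core import GridSpec, Raster
from healthaccess.synthetic_data import SynthConfig, generate_world
from healthaccess.traveltime import SourceCells


@pytest.fixture
def spec3():
    return GridSpec(n_rows=3, n_cols=3, cell_size_m=1000.0, x_origin=0.0, y_origin=3000.0)


@pytest.fixture
def uniform_friction(spec3):
    return Raster(spec3, np.full((3, 3), 0.03), "friction")


def make_random_friction(rng, n_rows, n_cols, cell_size_m=1000.0, nodata_frac=0.0):
    f = np.exp(rng.uniform(np.log(0.01), np.log(0.1), size=(n_rows, n_cols)))
    if nodata_frac > 0:
        f[rng.random((n_rows, n_cols)) < nodata_frac] = np.nan
    spec = GridSpec(n_rows, n_cols, cell_size_m)
    return Raster(spec, f, "friction")


def make_sources(spec, cells):
    return SourceCells(spec, {tuple(c): [f"f{i}"] for i, c in enumerate(cells)})


def random_sources(rng, friction, k):
    valid = np.argwhere(friction.valid_mask)
    picks = valid[rng.choice(len(valid), size=min(k, len(valid)), replace=False)]
    return make_sources(friction.spec, [tuple(map(int, p)) for p in picks])


@pytest.fixture(scope="session")
def world42():
    """The default synthetic world, shared across the session (read-only)."""
    return generate_world(SynthConfig(seed=42))


@pytest.fixture(scope="session")
def small_world():
    """A 48x48 world for the faster end-to-end checks."""
    cfg = SynthConfig(
        seed=21,
        n_rows=48,
        n_cols=48,
        n_zones=4,
        n_urban_clusters=4,
        facility_counts={"PCC": 20, "TH": 5, "DH": 8, "CHC": 20, "PHC": 60},
    )
    return generate_world(cfg)
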