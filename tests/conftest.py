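import numpy as np
import pytest

from lffcouple.synthetic_cohort import (
    CohortSpec,
    cohort_geometry,
    generate_cohort,
    small_spec,
)
from lffcouple.volumes_io import MaskSet


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Reduced-size cohort spec shared by the fast end-to-end tests."""
    return small_spec(n_per_group=5, seed=7)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    """One generated small cohort: (records, runs, masks, geometry)."""
    geom = cohort_geometry(tiny_spec)
    records, runs, masks = generate_cohort(tiny_spec)
    return records, runs, masks, geom


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture()
def box_masks() -> MaskSet:
    """A small hand-built mask set: 8x8x8 grid, nested compartments."""
    brain = np.zeros((8, 8, 8), dtype=bool)
    brain[1:7, 1:7, 1:7] = True
    inner = np.zeros_like(brain)
    inner[2:6, 2:6, 2:6] = True
    csf = brain & ~inner
    wm = np.zeros_like(brain)
    wm[3:5, 3:5, 3:5] = True
    gm = inner & ~wm
    return MaskSet(brain=brain, gm=gm, wm=wm, csf=csf)
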