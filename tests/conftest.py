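import numpy as np
import pytest

from cfqct.airway import MeasureParams, measure_tree
from cfqct.cohort import CohortTruth, simulate_cohort
from cfqct.phantoms import (
    TrappingSpec,
    make_airway_phantom,
    make_lobe_mask,
    make_paired_lung_phantom,
    single_tube_spec,
    six_lobe_tree_spec,
)


@pytest.fixture(scope="session")
def tube_4_1():
    """Noise-free cylinder: lumen 4 mm, wall 1 mm, 0.5 mm voxels."""
    spec = single_tube_spec(4.0, 1.0, length=20.0)
    grid, truth = make_airway_phantom(spec, 0.5)
    return grid, truth


@pytest.fixture(scope="session")
def measured_six_lobe():
    """A measured six-lobe tapering tree phantom (shared: expensive to build)."""
    spec = six_lobe_tree_spec()
    grid, truth = make_airway_phantom(spec, 0.6)
    measure_tree(grid, truth, MeasureParams(wall_hu=0.0))
    return grid, truth


@pytest.fixture(scope="session")
def paired_phantom():
    """Paired insp/exp lung phantom with a 10% RML defect and 5% LLL defect."""
    mask = make_lobe_mask()
    spec = TrappingSpec(defect_fractions={"RML": 0.10, "LLL": 0.05}, seed=42)
    return make_paired_lung_phantom(mask, spec)


@pytest.fixture(scope="session")
def cohort_df():
    return simulate_cohort(CohortTruth(seed=11))
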