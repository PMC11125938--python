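import numpy as np
import pytest

from mammocycle import CohortSpec, PhantomSpec, build_phantom, simulate_cohort
from mammocycle.volumetry import cohort_to_frame


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-sized phantom: 48^3 voxels, 26 mm breast, full anatomy."""
    return PhantomSpec(
        grid_shape=(48, 48, 48), breast_radius_mm=26.0, skin_thickness_mm=2.0,
        fg_margin_mm=5.0, n_lobules=6, duct_tree_depth=4,
        duct_branch_length_mm=5.0, duct_branch_radius_mm=1.8,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec, seed=1)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """Study-scale cohort (24 subjects, 48 breasts, 8 weekly visits)."""
    return cohort_to_frame(simulate_cohort(CohortSpec(seed=11)))
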