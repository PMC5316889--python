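import numpy as np
import pytest

import painsig as ps


@pytest.fixture(scope="session")
def grid12():
    return ps.make_grid((12, 12, 12), "ellipsoid")


@pytest.fixture(scope="session")
def truth12(grid12):
    return ps.make_ground_truth(grid12, seed=0)


@pytest.fixture(scope="session")
def reference12(grid12):
    return ps.generate_reference_signature(grid12, seed=2)


@pytest.fixture(scope="session")
def cohort(grid12, truth12):
    """Small synthetic cohort (8 subjects) for module-level tests."""
    design = ps.make_study_design("generic")
    return ps.generate_subjects(design, grid12, truth12, n_subjects=8, seed=1)


@pytest.fixture(scope="session")
def fitted_dev(cohort, reference12):
    return ps.SignatureDeveloper(reference_map=reference12).fit(cohort)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
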