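import numpy as np
import pytest

from lungshape.alignment import ShapeVector
from lungshape.synthetic import (
    GeneratorConfig,
    generate_cohort,
    template_lung_mesh,
)


@pytest.fixture(scope="session")
def template():
    return template_lung_mesh()


@pytest.fixture(scope="session")
def small_cohort():
    """12 synthetic subjects (truth meshes + clouds), shared across tests."""
    cfg = GeneratorConfig(n_subjects=12, seed=42)
    subjects, cov = generate_cohort(cfg)
    return subjects, cov, cfg


@pytest.fixture(scope="session")
def truth_shapes(small_cohort):
    subjects, _, _ = small_cohort
    return [ShapeVector.from_mesh(s.truth_mesh, s.subject_id) for s in subjects]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
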