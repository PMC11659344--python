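import numpy as np
import pytest

from srnapcr.quantify import ExpressionMatrix
from srnapcr.selection import LabeledMatrix
from srnapcr.synthetic import (
    CohortConfig,
    clinical_frame,
    counts_frame,
    make_reference_set,
    read_scale_feature_plans,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def refs():
    return make_reference_set(1)


@pytest.fixture(scope="session")
def default_cohort():
    """The study-sized cohort (30 pCR / 69 non-pCR) at a fixed seed."""
    return simulate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def labeled_matrix(default_cohort):
    matrix = ExpressionMatrix.from_counts(counts_frame(default_cohort))
    labels = clinical_frame(default_cohort)["group"]
    return LabeledMatrix(matrix=matrix, labels=labels)


@pytest.fixture(scope="session")
def read_scale_cohort():
    """Small-depth cohort whose counts are few enough to emit as FASTQ."""
    cfg = CohortConfig(n_pcr=2, n_nonpcr=3, features=read_scale_feature_plans(), seed=3)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
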