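import numpy as np
import pytest

from mitospectra import (
    CohortSpec,
    enumerate_all_protein_variants,
    generate_cohort,
    generate_score_table,
    load_default_annotation,
)


@pytest.fixture(scope="session")
def ann():
    """Bundled NC_012920.1 gene table on the synthetic reference sequence."""
    return load_default_annotation()


@pytest.fixture(scope="session")
def enum(ann):
    return enumerate_all_protein_variants(ann)


@pytest.fixture(scope="session")
def score_table(enum):
    return generate_score_table(enum, seed=424242)


@pytest.fixture(scope="session")
def ageing_like_cohort(ann):
    """One default (ageing-colon-like) synthetic cohort."""
    return generate_cohort(CohortSpec(), ann, seed=20121115)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
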