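import numpy as np
import pytest

from nvugib import algorithm
from nvugib.cohort import study_cohort, study_tables
from nvugib.synthetic import (
    SynthConfig,
    empirical_weights_from_cohort,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """The 115-patient study cohort reconstructed from the printed tables."""
    return study_cohort()


@pytest.fixture(scope="session")
def tables():
    return study_tables()


@pytest.fixture(scope="session")
def scores(cohort):
    """Aligned per-patient arrays: GBS, combined score, HREL label."""
    gbs = np.array([r.gbs for r in cohort])
    comb = np.array([
        algorithm.combined_score(r.gbs, r.bloody).value for r in cohort
    ])
    hrel = np.array([r.hrel for r in cohort])
    return gbs, comb, hrel


@pytest.fixture(scope="session")
def large_synthetic_cohort(cohort):
    """100k synthetic patients drawn from the study's empirical joint
    (GBS, bloody) weights per HREL stratum; shared across recovery tests."""
    cfg = SynthConfig(
        n_patients=100_000,
        gbs_distribution=empirical_weights_from_cohort(cohort, by_bloody=True),
        seed=20240915,
    )
    return generate_cohort(cfg)
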