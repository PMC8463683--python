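import numpy as np
import pandas as pd
import pytest

from metacheck.synthetic_cohort import (
    CohortConfig,
    SubjectProfile,
    make_glmm_cohort,
    simulate_implicit_pair,
    simulate_observer_trial,
    trials_to_frame,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def profile():
    return SubjectProfile("S000", sensitivity_k=2.5, meta_noise_sigma=0.4)


@pytest.fixture(scope="session")
def glmm_cohort():
    """One moderate GLMM-mode cohort shared across tests."""
    return make_glmm_cohort(CohortConfig(n_subjects=40, seed=7), n_trials=60)


@pytest.fixture(scope="session")
def explicit_trials():
    """Explicit-task trials from a mid-noise observer at one coherence."""
    rng = np.random.default_rng(21)
    prof = SubjectProfile("S000", sensitivity_k=2.5, meta_noise_sigma=0.4)
    trials = [
        simulate_observer_trial(prof, 0.4, "explicit", rng) for _ in range(4000)
    ]
    return trials_to_frame(trials)


def make_pairs(profile, n_pairs, rng, coherences=(0.05, 0.12, 0.2, 0.3, 0.45, 0.65), **kw):
    rows = []
    for j in range(n_pairs):
        ca, cb = rng.choice(np.asarray(coherences), size=2)
        a, b = simulate_implicit_pair(profile, float(ca), float(cb), rng, pair_id=j, **kw)
        rows.extend([a, b])
    return trials_to_frame(rows)


@pytest.fixture(scope="session")
def implicit_pairs():
    rng = np.random.default_rng(22)
    prof = SubjectProfile("S000", sensitivity_k=2.5, meta_noise_sigma=0.4)
    return make_pairs(prof, 4000, rng)


@pytest.fixture
def simple_poisson_frame(rng):
    n = 400
    x = rng.normal(size=n)
    y = rng.poisson(np.exp(0.2 + 0.4 * x))
    return pd.DataFrame({"y": y, "x": x, "subject_id": "a"})
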