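"""Shared fixtures: seeded RNGs and session-scoped synthetic cohorts.

The expensive artifacts (window feature tables) are built once per session
and shared by the classification and acceptance tests.
"""

import numpy as np
import pytest

from emgsynergy import pipeline
from emgsynergy.synthetic_data import SynthSpec, generate_cohort

COHORT_SEED = 7


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def motion_cohort():
    """Two subjects per group, two repetitions, all three motions."""
    spec = SynthSpec(n_subjects=2, reps=2, seed=COHORT_SEED)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def motion_table(motion_cohort):
    """Fine k=2 window feature table for motion recognition."""
    _, cohort = motion_cohort
    recs = [r for r, _ in cohort]
    return pipeline.build_feature_table(
        recs, k=2, feature_set="fine", label_by="motion", seed=0
    )


@pytest.fixture(scope="session")
def pathology_table():
    """Fine k=2 feature table for the binary pathology task (ST motion)."""
    spec = SynthSpec(n_subjects=3, reps=4, seed=COHORT_SEED)
    cohort = generate_cohort(spec, motions=("ST",))
    recs = [r for r, _ in cohort]
    return pipeline.build_feature_table(
        recs, k=2, feature_set="fine", label_by="group", seed=0
    )


def split_xy(table):
    names = [
        c for c in table.columns if c not in ("label", "subject_id", "group", "motion")
    ]
    return table[names].to_numpy(), table["label"].to_numpy(), names
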