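import numpy as np
import pandas as pd
import pytest

from paytoknow.cohort import CohortConfig, simulate_cohort, simulate_subject
from paytoknow.parameters import SubjectParameters
from paytoknow.task import build_task_schedule, records_to_frame


@pytest.fixture(scope="session")
def schedule():
    return build_task_schedule(seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 6-subject social cohort with its hidden truth table."""
    cfg = CohortConfig(n_subjects=6, cohort_seed=11, schedule_seed=3)
    data, truth = simulate_cohort(cfg)
    return data, truth


@pytest.fixture(scope="session")
def homogeneous_frame(schedule):
    """Choices from 8 identical moderately-noisy agents (beta = 0.35)."""
    p = SubjectParameters(alpha=1.0, beta_pos=0.35, beta_neg=0.35,
                          gamma=6.0, epsilon=0.08)
    recs = []
    for i in range(8):
        recs += simulate_subject(schedule, p, seed=100 + i, subject_id=f"s{i:02d}")
    return records_to_frame(recs)


@pytest.fixture(scope="session")
def deterministic_frame(schedule):
    """Lapse-free, near-deterministic agents: choices depend only on the design."""
    p = SubjectParameters(alpha=1.0, beta_pos=0.35, beta_neg=0.35,
                          gamma=30.0, epsilon=0.0)
    recs = []
    for i in range(5):
        recs += simulate_subject(schedule, p, seed=i, subject_id=f"d{i:02d}")
    return records_to_frame(recs)
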