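import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cpmkit import CohortDataset, SyntheticSpec, simulate_cohort

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


def make_cohort(edge_matrix, score, age=None, motion=None, node_count=None):
    """Assemble a CohortDataset from raw arrays (covariates default to benign values)."""
    edge_matrix = np.asarray(edge_matrix, dtype=float)
    n = edge_matrix.shape[0]
    rng = np.random.default_rng(99)
    if age is None:
        age = rng.uniform(5, 14, n)
    if motion is None:
        motion = rng.uniform(0.05, 0.25, n)
    if node_count is None:
        # invert E = m(m-1)/2
        E = edge_matrix.shape[1]
        node_count = int((1 + np.sqrt(1 + 8 * E)) / 2)
    return CohortDataset(
        edge_matrix=edge_matrix,
        score=np.asarray(score, dtype=float),
        covariates=pd.DataFrame({"age": age, "motion": motion}),
        subject_ids=tuple(f"s{i:03d}" for i in range(n)),
        node_count=node_count,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted-signal cohort used across modules."""
    spec = SyntheticSpec(
        n_subjects=24,
        n_nodes=10,
        n_signal_pos=4,
        n_signal_neg=4,
        signal_scale=1.0,
        seed=11,
    )
    return simulate_cohort(spec)
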