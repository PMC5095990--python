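import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from stromascan import ExpressionMatrix, SimulationConfig, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_expr(values, genes=None, samples=None, scale_tag="log2p1"):
    values = np.asarray(values, dtype=float)
    if scale_tag == "log2p1":
        values = np.clip(values, 0.0, None)
    genes = genes or [f"G{i+1}" for i in range(values.shape[0])]
    samples = samples or [f"S{j+1}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                            scale_tag)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size cohort with all gene classes, reused read-only."""
    return generate_cohort(SimulationConfig(n_samples=300, n_candidate_genes=5,
                                            seed=42))
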