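import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from immunonet import simulate as sim  # noqa: E402


@pytest.fixture(scope="session")
def default_spec():
    return sim.CohortSpec(seed=0)


@pytest.fixture(scope="session")
def default_truth(default_spec):
    return sim.generate_truth(default_spec)


@pytest.fixture(scope="session")
def cohort_pair(default_spec, default_truth):
    return sim.generate_cohort_pair(default_spec, default_truth)


@pytest.fixture(scope="session")
def gene_expr(cohort_pair):
    """Cohort-1 / cohort-2 expression restricted to non-TF genes."""
    coh1, coh2, _, _ = cohort_pair
    genes = [g for g in coh1.expr.index if not g.startswith("TF")]
    return coh1.expr.loc[genes], coh2.expr.loc[genes]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def two_block_expr(n_per_block=10, n_samples=40, noise=0.0, seed=0):
    """Two disjoint tightly co-expressed gene blocks (helper for module tests)."""
    r = np.random.default_rng(seed)
    f1, f2 = r.standard_normal(n_samples), r.standard_normal(n_samples)
    rows = {}
    for i in range(n_per_block):
        rows[f"A{i}"] = f1 * (1 + 0.01 * i) + noise * r.standard_normal(n_samples)
    for i in range(n_per_block):
        rows[f"B{i}"] = f2 * (1 + 0.01 * i) + noise * r.standard_normal(n_samples)
    return pd.DataFrame(rows).T
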