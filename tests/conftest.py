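import numpy as np
import pandas as pd
import pytest

from hccpanel import ExpressionDataset, SimulationSpec, simulate_cohorts
from hccpanel.expression_io import NORMAL, TUMOR


@pytest.fixture(scope="session")
def standard_sim():
    """Reference simulation shared across tests: 12 cohorts (10 discovery,
    1 training, 1 validation by convention), 1,000 genes, 20 planted."""
    spec = SimulationSpec(n_cohorts=12, seed=42, paired_fraction=0.2)
    datasets, truth = simulate_cohorts(spec)
    return spec, datasets, truth


@pytest.fixture
def toy_dataset():
    """Tiny 4-gene two-class cohort with one clean separator (G_sep)."""
    rng = np.random.default_rng(0)
    n = 20
    genes = ["G_sep", "G_null1", "G_null2", "G_weak"]
    tumor = np.vstack(
        [
            rng.normal(10, 0.5, n),  # well above normal
            rng.normal(7, 1.0, n),
            rng.normal(5, 1.0, n),
            rng.normal(8.0, 1.0, n),
        ]
    )
    normal = np.vstack(
        [
            rng.normal(6, 0.5, n),
            rng.normal(7, 1.0, n),
            rng.normal(5, 1.0, n),
            rng.normal(7.2, 1.0, n),
        ]
    )
    t_ids = [f"T{i}" for i in range(n)]
    n_ids = [f"N{i}" for i in range(n)]
    values = pd.DataFrame(np.hstack([tumor, normal]), index=genes, columns=t_ids + n_ids)
    labels = pd.Series([TUMOR] * n + [NORMAL] * n, index=t_ids + n_ids)
    return ExpressionDataset(cohort_id="toy", values=values, labels=labels)
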