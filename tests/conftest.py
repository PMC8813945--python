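import numpy as np
import pandas as pd
import pytest

from regmeth.cohort import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_bundle():
    """Moderate cohort with planted effects, shared across tests."""
    cfg = SyntheticConfig(
        n_pairs=12,
        n_promoters=300,
        n_enhancers=400,
        n_genes=1200,
        n_super_enhancers=30,
        n_snps=60,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def paired_samples():
    """8 patients, complete tumor/normal pairs."""
    rows = []
    for i in range(8):
        rows.append({"sample_id": f"P{i}_T", "patient_id": f"P{i}", "tissue": "tumor"})
        rows.append({"sample_id": f"P{i}_N", "patient_id": f"P{i}", "tissue": "normal"})
    return pd.DataFrame(rows)
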