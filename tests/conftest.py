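import numpy as np
import pandas as pd
import pytest

from mirpair.synthetic import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete synthetic cohort with ground truth."""
    cfg = default_config(
        n_subjects=40, n_genes=80, n_pathway_genes=10, n_mirnas=20,
        n_couplings=4, seed=123)
    return generate_cohort(cfg)


@pytest.fixture()
def paired_metadata():
    """Hand-built metadata for 6 subjects (2 MSI), alternating sex."""
    rows = []
    for i in range(6):
        for status in ("tumor", "normal"):
            rows.append({
                "sample_id": f"s{i}{'T' if status == 'tumor' else 'N'}",
                "subject_id": f"subj{i}", "tissue_status": status,
                "age": 60.0 + i, "sex": "M" if i % 2 == 0 else "F",
                "msi_status": "MSI" if i < 2 else "MSS"})
    return pd.DataFrame(rows)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
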