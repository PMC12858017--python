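import numpy as np
import pandas as pd
import pytest

import pvsignal as pv


@pytest.fixture
def toy_reports() -> pv.ReportCountTable:
    """Six-cell report table with one clearly disproportionate signal.

    (D1, S1) has a=20, b=5, c=5, d=70, hence ROR=56 and PRR=12.
    """
    return pv.ReportCountTable(
        pd.DataFrame(
            {
                "drug_id": ["D1", "D1", "D2", "D2", "D3", "D3"],
                "soc": ["S1", "S2", "S1", "S2", "S1", "S2"],
                "count": [20, 5, 2, 40, 3, 30],
            }
        )
    )


@pytest.fixture(scope="session")
def small_world() -> pv.SyntheticWorld:
    """A compact planted world shared by fast structural tests."""
    cfg = pv.SyntheticConfig(
        n_drugs=120,
        n_targets=40,
        soc_names=(
            "Psychiatric disorders",
            "Cardiac disorders",
            "Eye disorders",
        ),
        causal_targets_per_soc=4,
        interaction_density=0.12,
        relative_risk=6.0,
        seed=11,
    )
    return pv.generate_world(cfg)


def random_label_matrix(rng: np.random.Generator, n_drugs=6, n_socs=4, p=0.3):
    drugs = [f"D{i}" for i in range(n_drugs)]
    socs = [f"S{j}" for j in range(n_socs)]
    labels = (rng.random((n_drugs, n_socs)) < p).astype(int)
    return pv.SignalLabelMatrix(drug_ids=drugs, socs=socs, labels=labels)
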