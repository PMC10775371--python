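import numpy as np
import pandas as pd
import pytest

from glandmap import SynthConfig, example_signature, synth_expression


@pytest.fixture(scope="session")
def signature():
    return example_signature()


@pytest.fixture(scope="session")
def small_expression():
    """100-cell fixture with 7 disjoint planted QC violations."""
    cfg = SynthConfig(
        seed=11,
        n_patients_per_group=1,
        n_cells_per_patient=50,
        qc_violation_rates={
            "mito": 0.02,
            "ribo": 0.01,
            "hb": 0.01,
            "low_genes": 0.02,
            "low_counts": 0.01,
        },
    )
    adata, truth = synth_expression(cfg)
    return adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_spots():
    """Deterministic 6-spot table, two groups, 3 types."""
    rows = []
    for g, xs in (("SjD", 0.0), ("nonSjD", 100.0)):
        for i in range(3):
            rows.append(
                {"spot_id": f"{g}{i}", "x": xs + i, "y": 0.0, "group": g,
                 "A": 0.5, "B": 0.3, "C": 0.2}
            )
    return pd.DataFrame(rows)
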