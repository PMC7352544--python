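import numpy as np
import pandas as pd
import pytest

from hoxpress import (
    CohortPair,
    CorrelationBlock,
    ExpressionMatrix,
    SimulationConfig,
    SurvivalConfig,
    build_catalog,
    generate,
)


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def planted_cohort():
    """Synthetic cohort with planted fold changes, a correlation block and a
    survival-linked gene; shared read-only across tests."""
    config = SimulationConfig(
        n_tumor=150,
        n_healthy=120,
        fold_changes={"HOXA13": 4.0, "HOXB9": 3.0, "HOXC10": 0.25, "HOXB5": 4.0, "HOXB6": 4.0},
        correlation_blocks=(CorrelationBlock(("HOXB5", "HOXB6", "HOXB7"), 0.8),),
        survival=SurvivalConfig(lambda0=1e-3, beta={"HOXA13": 0.9}, censoring_rate=0.2),
        seed=20240614,
    )
    return generate(config)


def make_cohort_pair(healthy: np.ndarray, tumor: np.ndarray, genes=None, category="TEST"):
    """Wrap raw arrays (genes x samples) into a CohortPair."""
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(healthy.shape[0])]
    h = pd.DataFrame(healthy, index=genes, columns=[f"H{i}" for i in range(healthy.shape[1])])
    t = pd.DataFrame(tumor, index=genes, columns=[f"T{i}" for i in range(tumor.shape[1])])
    return CohortPair(category, ExpressionMatrix(t), ExpressionMatrix(h))
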