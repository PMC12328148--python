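import numpy as np
import pandas as pd
import pytest

from memtarget import (
    ClinicalTable,
    CompartmentAnnotation,
    ExpressionMatrix,
    OffTumorProfile,
    SimulationConfig,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort shared across tests."""
    return simulate_cohort(SimulationConfig(seed=7))


@pytest.fixture
def tiny_matrix():
    """3 features x 6 samples, one feature with a missing cell."""
    data = pd.DataFrame(
        {
            "S1": [1.0, 5.0, 2.0],
            "S2": [2.0, 5.5, np.nan],
            "S3": [3.0, 4.5, 2.2],
            "S4": [4.0, 5.2, 1.9],
            "S5": [5.0, 4.8, 2.1],
            "S6": [6.0, 5.1, 2.0],
        },
        index=["f_linear", "f_flat", "f_gap"],
    )
    return ExpressionMatrix(data, "proteome")


@pytest.fixture
def tiny_clinical():
    return ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S3", "S4", "S5", "S6", "N1"],
                "tissue": ["tumor"] * 6 + ["adjacent_normal"],
                "ln_status": ["metastatic"] * 3 + ["non_metastatic"] * 3 + ["unknown"],
                "os_time": [100, 200, 300, 400, 500, 600, 0],
                "os_event": [1, 0, 1, 0, 1, 0, 0],
                "pfs_time": [80, 150, 250, 350, 450, 550, 0],
                "pfs_event": [1, 1, 0, 0, 1, 0, 0],
            }
        )
    )


@pytest.fixture
def membrane_annotation():
    return CompartmentAnnotation(
        {
            "f_linear": {"membrane"},
            "f_flat": {"membrane", "nucleus"},
            "f_gap": {"cytosol"},
        }
    )


@pytest.fixture
def tiny_offtumor():
    return OffTumorProfile(
        pd.DataFrame(
            {
                "liver": [0.0, 20.0, 3.0],
                "lung": [0.0, 55.0, 0.5],
            },
            index=["f_linear", "f_flat", "f_gap"],
        )
    )
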