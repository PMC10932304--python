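import numpy as np
import pandas as pd
import pytest

from dili_ternary import PeakTable, SampleRecord, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort with ground truth, shared across tests."""
    cfg = SimulationConfig(n_patients=24, n_features=120, n_informative_c=15,
                           n_informative_h=15, drift_amplitude=0.0, seed=11)
    return simulate_cohort(cfg)


@pytest.fixture
def toy_peak_table():
    """3 study samples + 1 QC x 4 features, one missing cell."""
    intens = pd.DataFrame(
        [[100.0, 200.0, 300.0, 400.0],
         [110.0, np.nan, 310.0, 410.0],
         [120.0, 220.0, 320.0, 420.0],
         [105.0, 205.0, 305.0, 405.0]],
        index=pd.Index(["S1", "S2", "S3", "QC1"], name="sample_id"),
        columns=["f1", "f2", "f3", "f4"])
    return PeakTable(
        intensities=intens,
        batch=pd.Series(["B1"] * 4, index=intens.index),
        injection_order=pd.Series([1, 2, 3, 4], index=intens.index),
        role=pd.Series(["study", "study", "study", "qc"], index=intens.index))


@pytest.fixture
def toy_records():
    return [
        SampleRecord("S1", "P1", 1, alt=30.0, alp=100.0, bilirubin=0.5),
        SampleRecord("S2", "P1", 2, alt=200.0, alp=120.0, bilirubin=1.0),
        SampleRecord("S3", "P2", 1, alt=20.0, alp=300.0, bilirubin=2.0),
    ]


def drift_fixture(seed: int = 3) -> tuple:
    """Single-batch cohort used by the drift-correction checks."""
    cfg = SimulationConfig(n_patients=12, n_features=40, n_informative_c=5,
                           n_informative_h=5, n_batches=1, qc_every=5,
                           drift_amplitude=0.0, missing_rate=0.02,
                           qc_noise_sd=0.05, seed=seed)
    cohort, truth = simulate_cohort(cfg)
    return cohort.peak_table, truth
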