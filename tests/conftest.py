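import numpy as np
import pandas as pd
import pytest

from adminqc import PanelDataset
from adminqc.synthetic import SyntheticConfig, simulate_panel


def make_panel(rows, columns=("id", "month"), **kwargs) -> PanelDataset:
    """Panel from a list of row tuples; first two columns are id and month."""
    df = pd.DataFrame(rows, columns=list(columns))
    return PanelDataset.from_frame(df, id_var=columns[0], time_var=columns[1], **kwargs)


def month(i: int, start_year: int = 2011) -> str:
    return f"{start_year + i // 12:04d}-{i % 12 + 1:02d}"


@pytest.fixture(scope="session")
def clean_panel():
    """Small defect-free synthetic panel shared across read-only tests."""
    panel, truth = simulate_panel(SyntheticConfig(n_units=400, seed=101))
    assert truth.total == 0
    return panel


@pytest.fixture(scope="session")
def defect_panel_with_truth():
    """Synthetic panel with every defect class injected (no outliers, so
    mean-based shift checks stay interpretable)."""
    cfg = SyntheticConfig(
        n_units=2000,
        seed=202,
        invalid_id_rate=0.02,
        duplicate_rate=0.005,
        missing_rates={"single_parent": 0.15, "two_parent": 0.05},
        stable_flip_rate=0.01,
        monotone_violation_rate=0.01,
    )
    return simulate_panel(cfg), cfg


@pytest.fixture
def rng():
    return np.random.default_rng(20_260_923)
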