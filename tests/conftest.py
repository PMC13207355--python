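import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from phenoscreen import ScreenConfig, preprocess_screen, simulate_screen


@pytest.fixture(scope="session")
def small_screen():
    """Two-plate, 120-feature screen with 10% active compounds."""
    cfg = ScreenConfig(n_plates=2, n_features=120, seed=7, fraction_null=0.9)
    table, truth = simulate_screen(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def scaled_screen(small_screen):
    _, table, truth = small_screen
    scaled, report = preprocess_screen(table)
    return scaled, truth, report


@pytest.fixture
def tiny_feature_csv(tmp_path):
    """4-well, 3-feature CSV in CellProfiler-style layout."""
    df = pd.DataFrame({
        "Metadata_Plate": ["P01"] * 4,
        "Metadata_Well": ["A01", "A02", "B1", "B02"],
        "Metadata_Role": ["dmso", "dmso", "sample", "sample"],
        "feat_a": [1.0, 2.0, 3.0, 4.0],
        "feat_b": [0.5, 0.5, 0.5, 0.5],
        "feat_c": [-1.0, 0.0, 1.0, 2.0],
    })
    path = tmp_path / "features.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def plate_map_csv(tmp_path):
    rows = []
    for i in range(48):
        rows.append(("P01", f"{chr(65 + i // 24)}{i % 24 + 1:02d}", "E13", "", "", "DMSO"))
    rows.append(("P01", "D01", "E13", "cpd1", "3000", "sample"))
    df = pd.DataFrame(rows, columns=["plate", "well", "cell_line", "compound",
                                     "dose_nM", "role"])
    path = tmp_path / "platemap.csv"
    df.to_csv(path, index=False)
    return path
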