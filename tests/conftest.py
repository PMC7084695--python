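import numpy as np
import pandas as pd
import pytest

from aapanel.panel import AnalytePanel, META_COLUMNS


def build_panel(X, y, analyte_names=None, timepoints=None, **meta_overrides):
    """Assemble an AnalytePanel from a raw matrix and labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n, p = X.shape
    if analyte_names is None:
        analyte_names = [f"A{j:02d}" for j in range(p)]
    frame = pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n)],
            "animal_id": [f"P{i:03d}" for i in range(n)],
            "label": y,
            "timepoint": timepoints if timepoints is not None
            else np.where(y == 1, "24h", "pre"),
            "injury_model": np.where(y == 1, "RNR", "none"),
            "compartment": "serum",
        }
    )
    for key, val in meta_overrides.items():
        frame[key] = val
    for j, name in enumerate(analyte_names):
        frame[name] = X[:, j]
    return AnalytePanel(frame, list(analyte_names))


@pytest.fixture
def rng():
    return np.random.default_rng(20240317)


@pytest.fixture
def small_panel(rng):
    """30-sample, 4-analyte panel with one informative analyte."""
    n = 30
    y = np.repeat([0, 1], n // 2)
    X = rng.normal(100.0, 20.0, size=(n, 4))
    X[:, 1] += 40.0 * y  # A01 carries the signal
    X = np.abs(X)
    return build_panel(X, y)


@pytest.fixture
def meta_columns():
    return META_COLUMNS
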