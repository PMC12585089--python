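import numpy as np
import pandas as pd
import pytest

BASE_ROW = {
    "date": "2010-08-01",
    "lat": 70.0,
    "lon": 15.0,
    "depth_m": 30.0,
    "taxon": "Astarte borealis",
    "phylum": "Mollusca",
    "genus": "Astarte",
    "group": "consumer",
    "habit": "suspension feeder",
    "d13C": -21.0,
    "d15N": 9.0,
    "treatment": "none",
}


def make_csv(path, rows):
    """Write a records CSV from partial row dicts (defaults filled)."""
    filled = [{**BASE_ROW, **row} for row in rows]
    pd.DataFrame(filled).to_csv(path, index=False)
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture
def records_csv(tmp_path):
    def _make(rows, name="records.csv"):
        return make_csv(tmp_path / name, rows)

    return _make
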