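import pandas as pd
import pytest

from toxsar.chem import load_panel


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def panel_by_id(panel):
    return {c.id: c for c in panel}


@pytest.fixture()
def well_table():
    """Noise-free plate: vehicle 0.20, positive 0.90, one treatment at 50%."""
    rows = []
    for condition, signal in [("vehicle", 0.20), ("positive", 0.90), ("t50", 0.55)]:
        for rep in (1, 2, 3):
            for read in (1, 2, 3):
                rows.append(
                    {
                        "condition": condition,
                        "replicate": rep,
                        "read_index": read,
                        "a_meas": signal + 0.05,
                        "a_ref": 0.05,
                    }
                )
    return pd.DataFrame(rows)
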