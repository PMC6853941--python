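import numpy as np
import pandas as pd
import pytest

from perturbome.normalize import WellFeatureTable


def make_meta(rows):
    """Build a (plate, well)-indexed metadata frame from dict rows."""
    defaults = {
        "row": 0, "col": 0, "batch": 0, "role": "control",
        "drug_a": "", "drug_b": "", "replicate": 1, "time_order": 1,
        "cell_count": 100,
    }
    records = [{**defaults, **r} for r in rows]
    return pd.DataFrame(records).set_index(["plate", "well"])


def make_wells(values: np.ndarray, meta: pd.DataFrame, features=None, **flags):
    features = features or [f"f{i}" for i in range(values.shape[1])]
    return WellFeatureTable(
        values=pd.DataFrame(values, index=meta.index, columns=features),
        meta=meta,
        **flags,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid_meta():
    """One full 6x8 plate of control wells."""
    rows = []
    for r in range(6):
        for c in range(8):
            rows.append({"plate": "P0", "well": f"{r}-{c}", "row": r, "col": c})
    return make_meta(rows)
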