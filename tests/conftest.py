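import numpy as np
import pandas as pd
import pytest

from epimr import harmonize, load_fabp4_instruments


@pytest.fixture(scope="session")
def fabp4():
    """Packaged three-SNP instrument fixture: (exposure, outcome) records."""
    return load_fabp4_instruments()


@pytest.fixture(scope="session")
def fabp4_set(fabp4):
    exposure, outcome = fabp4
    return harmonize(exposure, outcome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_pairs(diffs, base=None):
    """1:1 matched-set frame from case-minus-control differences of one covariate."""
    rows = []
    for i, d in enumerate(diffs):
        b = 0.0 if base is None else base[i]
        rows.append({"set_id": f"s{i}", "is_case": 1, "x": b + d})
        rows.append({"set_id": f"s{i}", "is_case": 0, "x": b})
    return pd.DataFrame(rows)
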