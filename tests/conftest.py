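import numpy as np
import pandas as pd
import pytest

from _designs import planted_config


@pytest.fixture
def small_expr():
    """3 genes x 6 samples across 3 tissues, hand-sized."""
    genes = pd.Index(["G1", "G2", "G3"], name="Name")
    samples = pd.Index([f"S{i}" for i in range(6)], name="SAMPID")
    values = np.array(
        [
            [1.0, 3.0, 4.0, 6.0, 10.0, 10.0],
            [2.0, 2.0, 2.0, 2.0, 2.0, 2.0],
            [0.0, 0.0, 5.0, 5.0, 0.0, 1.0],
        ]
    )
    return pd.DataFrame(values, index=genes, columns=samples)


@pytest.fixture
def small_design(small_expr):
    return pd.DataFrame(
        {
            "tissue": ["T1", "T1", "T2", "T2", "T3", "T3"],
            "donor": [f"D{i}" for i in range(6)],
            "rin": [7.0] * 6,
        },
        index=small_expr.columns,
    )


@pytest.fixture
def noiseless_config():
    return planted_config(cv=0.0)
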