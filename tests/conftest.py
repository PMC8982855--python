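import numpy as np
import pandas as pd
import pytest

from ovatools.io import CountMatrix


@pytest.fixture
def toy_count_matrix() -> CountMatrix:
    counts = pd.DataFrame(
        {
            "s1": [10, 200, 0, 35],
            "s2": [12, 180, 1, 40],
            "s3": [8, 220, 0, 30],
            "s4": [11, 210, 2, 38],
        },
        index=["fa", "fb", "fc", "fd"],
    )
    sample_meta = pd.DataFrame(
        {"genotype": ["WT", "WT", "mut", "mut"], "replicate": [1, 2, 1, 2]},
        index=counts.columns,
    )
    feature_meta = pd.DataFrame(
        {
            "length": [1000, 2000, 500, 1500],
            "gc_fraction": [0.35, 0.45, 0.55, 0.60],
            "class": ["gene"] * 4,
        },
        index=counts.index,
    )
    return CountMatrix(counts, sample_meta, feature_meta)
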