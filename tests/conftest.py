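import numpy as np
import pandas as pd
import pytest

from ariomics.diffsig import OmicsMatrix
from ariomics.synthetic import SimDesign, gen_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """300-feature two-format proteome with planted 5% signature."""
    design = SimDesign(n_features=300, frac_signature=0.05, seed=42)
    mats, truth = gen_proteome(design)
    return mats, truth, design


@pytest.fixture()
def tiny_matrix():
    """Two groups x 3 replicates, 3 features, hand-set values."""
    cols = [f"{g}_r{i}" for g in ("WT", "KO") for i in (1, 2, 3)]
    values = pd.DataFrame(
        {
            cols[0]: [100.0, 50.0, 80.0],
            cols[1]: [110.0, 55.0, 82.0],
            cols[2]: [90.0, 45.0, 78.0],
            cols[3]: [200.0, 50.0, 160.0],
            cols[4]: [220.0, 55.0, 164.0],
            cols[5]: [180.0, 45.0, 156.0],
        },
        index=["up2x", "flat", "up2x_b"],
    )
    design = pd.DataFrame(
        {
            "group": ["WT"] * 3 + ["KO"] * 3,
            "format": "2D",
            "replicate": [1, 2, 3, 1, 2, 3],
        },
        index=pd.Index(cols, name="sample"),
    )
    return OmicsMatrix(values, design, reference="WT")


def make_matrix(data: dict, groups: dict, reference: str = "WT") -> OmicsMatrix:
    """Build an OmicsMatrix from {feature: row} and {sample: group}."""
    values = pd.DataFrame(data, index=list(groups)).T
    design = pd.DataFrame(
        {"group": list(groups.values()), "format": "x", "replicate": range(len(groups))},
        index=pd.Index(list(groups), name="sample"),
    )
    return OmicsMatrix(values, design, reference=reference)
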