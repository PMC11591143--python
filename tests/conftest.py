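import numpy as np
import pandas as pd
import pytest

from ch4rumen.community import ASVTable


@pytest.fixture
def tiny_table() -> ASVTable:
    """4 samples x 5 ASVs with groups and lineages, small enough to check
    every aggregate by hand."""
    counts = pd.DataFrame(
        [
            [3, 0, 1, 5, 0],
            [4, 2, 0, 5, 0],
            [0, 0, 2, 5, 1],
            [0, 0, 3, 5, 2],
        ],
        index=["L1", "L2", "H1", "H2"],
        columns=["a1", "a2", "a3", "a4", "a5"],
    )
    groups = pd.Series(["LME", "LME", "HME", "HME"], index=counts.index)
    lineages = pd.Series(
        {
            "a1": "k__Bacteria; p__Firmicutes; c__Clostridia; o__; f__; g__GenA",
            "a2": "k__Bacteria; p__Firmicutes; c__Clostridia; o__; f__; g__GenB",
            "a3": "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__; f__; g__GenC",
            "a4": "k__Bacteria; p__Bacteroidetes",
            "a5": "",
        }
    )
    return ASVTable(counts=counts, groups=groups, lineages=lineages)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
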