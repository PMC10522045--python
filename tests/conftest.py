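import numpy as np
import pandas as pd
import pytest

from signda import CountTable, SampleMetadata, user_reference_frame


@pytest.fixture
def tiny_table():
    """3 taxa x 2 samples with known column sums (3, 8)."""
    return CountTable(
        pd.DataFrame(
            [[1, 0], [2, 5], [0, 3]],
            index=["tA", "tB", "tC"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture
def small_dataset():
    """12 taxa x 20 samples, two balanced groups, reproducible counts."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(0, 40, (12, 20)),
        index=[f"t{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(20)],
    )
    table = CountTable(counts)
    meta = SampleMetadata(
        pd.DataFrame(
            {
                "group": [0] * 10 + [1] * 10,
                "library_size": table.library_sizes.astype(float),
            },
            index=counts.columns,
        )
    )
    rf = user_reference_frame(table, ["t0", "t1", "t2"])
    return table, meta, rf


@pytest.fixture
def constant_library_dataset():
    """Same shape but with a constant library size, for equality reductions."""
    rng = np.random.default_rng(11)
    counts = pd.DataFrame(
        rng.integers(0, 40, (12, 20)),
        index=[f"t{i}" for i in range(12)],
        columns=[f"s{i}" for i in range(20)],
    )
    table = CountTable(counts)
    meta = SampleMetadata(
        pd.DataFrame(
            {"group": [0] * 10 + [1] * 10, "library_size": np.full(20, 500.0)},
            index=counts.columns,
        )
    )
    rf = user_reference_frame(table, ["t0", "t1", "t2"])
    return table, meta, rf
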