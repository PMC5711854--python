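import numpy as np
import pandas as pd
import pytest

from microkit import OtuTable, SampleMetadata


def make_metadata(sample_ids, groups, subjects=None, timepoints=0, housing="sh"):
    n = len(sample_ids)
    if np.isscalar(timepoints):
        timepoints = [timepoints] * n
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": groups,
                "subject": subjects if subjects is not None else sample_ids,
                "timepoint": timepoints,
                "housing": housing,
            }
        )
    )


@pytest.fixture
def two_group_meta():
    """Builder for simple two-group metadata."""
    return make_metadata


@pytest.fixture
def small_table():
    """4 samples x 3 OTUs with distinct totals."""
    counts = np.array([[1, 1, 2], [4, 0, 0], [2, 2, 0], [7, 0, 3]])
    return OtuTable(["s1", "s2", "s3", "s4"], ["o1", "o2", "o3"], counts)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
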