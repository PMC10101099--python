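import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microstab import (OtuTable, PhyloTree, StudyMetadata,
                       make_study_fixture)


@pytest.fixture
def small_table():
    counts = np.array([[10, 0, 5, 1],
                       [0, 8, 2, 6],
                       [4, 4, 4, 4]])
    return OtuTable(counts, ["s1", "s2", "s3"], ["A", "B", "C", "D"])


@pytest.fixture
def four_leaf_tree():
    t = TreeNode.read(io.StringIO("((A:1,B:1):0.5,(C:1,D:1):0.5);"))
    return PhyloTree(t)


@pytest.fixture
def star_tree():
    t = TreeNode.read(io.StringIO("(A:1,B:1,C:1,D:1);"))
    return PhyloTree(t)


@pytest.fixture
def tiny_metadata():
    rows = []
    for p, smoking in (("P01", "nonsmoker"), ("P02", "smoker")):
        for w in range(1, 11):
            rows.append({"sample_id": f"{p}_W{w:02d}", "participant_id": p,
                         "week": w, "smoking": smoking, "health": "healthy",
                         "sex": "female", "age": 25})
    return StudyMetadata(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def small_fixture():
    """6 participants x 12 weeks; shared by the pipeline-level tests."""
    return make_study_fixture(participants=6, weeks=12, n_core=6, seed=3)
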