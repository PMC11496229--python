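import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from siakit import OutcomeMatrix


@pytest.fixture
def small_matrix():
    """Six subjects, two outcomes, no missing values."""
    return OutcomeMatrix(
        subject_ids=[f"p{i}" for i in range(6)],
        outcome_names=["work", "living"],
        values=np.array([[1, 1], [1, 0], [0, 1], [0, 0], [1, 1], [0, 1]], float),
    )


@pytest.fixture
def csv_file(tmp_path):
    path = tmp_path / "outcomes.csv"
    path.write_text(
        "id,work,living,sympt,base\n"
        "p1,1,1,0,1\n"
        "p2,0,1,1,0\n"
        "p3,1,NA,1,0\n"
        "p4,0,0,0,1\n"
        "p5,1,1,1,\n"
    )
    return path
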