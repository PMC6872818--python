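import numpy as np
import pandas as pd
import pytest

from capsoqspr.data import validate_table


def make_table(rows):
    """Build a validated descriptor table from (Ec, Ne, Os, Ndb, Na, Nh, Nc, NN, E) tuples."""
    cols = ["Ec", "Ne", "Os", "Ndb", "Na", "Nh", "Nc", "NN", "E"]
    frame = pd.DataFrame(rows, columns=cols)
    frame.insert(0, "id", [f"m{i}" for i in range(len(frame))])
    return validate_table(frame)


@pytest.fixture
def tiny_table():
    """Six hand-written molecules spanning the energy range."""
    return make_table(
        [
            (2.81, 96, 0.41, 7, 33, 14, 16, 1, 2.85),
            (3.50, 74, 0.22, 5, 26, 12, 11, 1, 3.42),
            (4.31, 58, 0.35, 4, 21, 10, 9, 0, 4.25),
            (4.90, 88, 0.18, 3, 31, 15, 13, 2, 4.95),
            (5.62, 64, 0.55, 2, 24, 12, 10, 0, 5.70),
            (6.40, 46, 0.12, 1, 18, 9, 7, 1, 6.31),
        ]
    )
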