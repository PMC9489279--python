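import numpy as np
import pandas as pd
import pytest

from orsay_hostrange import assays, trees


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); -- height 2, MRCA(A,B) at depth 1."""
    return trees.parse_newick("((A:1,B:1):1,C:2);")


def make_ct_table(rows, undetected_ct=40.0):
    """rows: (strain, species, block, replicate, role, ct-or-None)."""
    frame = pd.DataFrame(
        rows, columns=["strain", "species", "block", "replicate", "role", "ct"]
    )
    frame["ct"] = frame["ct"].astype(float)
    return assays.CtTable(records=frame, undetected_ct=undetected_ct)


@pytest.fixture
def toy_ct_table():
    rows = [
        ("A", "spA", 1, 1, "experimental", 30.0),
        ("A", "spA", 1, 2, "experimental", 32.0),
        ("B", "spB", 1, 1, "experimental", None),
        ("B", "spB", 1, 2, "experimental", None),
        ("bm4", "C. elegans", 1, 1, "benchmark4", 33.6),
        ("bm4", "C. elegans", 1, 2, "benchmark4", 35.0),
        ("bm5", "C. elegans", 1, 1, "benchmark5", 22.0),
    ]
    return make_ct_table(rows)
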