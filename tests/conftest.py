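import io

import numpy as np
import pandas as pd
import pytest

from mirdx.ct_data import COLUMNS, CtTable


def make_table(rows, **kwargs) -> CtTable:
    """Build a CtTable from (sample_id, assay, specimen, group, timepoint,
    replicate, ct) tuples."""
    df = pd.DataFrame(rows, columns=COLUMNS)
    return CtTable(records=df, **kwargs)


@pytest.fixture
def duplicate_well_table() -> CtTable:
    """One cancer-plasma sample with duplicate wells for a marker and the
    reference gene, plus one control sample."""
    return make_table([
        ("s1", "miR-451", "plasma", "BC", "none", 1, 30.0),
        ("s1", "miR-451", "plasma", "BC", "none", 2, 30.4),
        ("s1", "RNU6B", "plasma", "BC", "none", 1, 24.1),
        ("s1", "RNU6B", "plasma", "BC", "none", 2, 23.9),
        ("s2", "miR-451", "plasma", "N", "none", 1, 32.0),
        ("s2", "miR-451", "plasma", "N", "none", 2, 32.2),
        ("s2", "RNU6B", "plasma", "N", "none", 1, 24.0),
        ("s2", "RNU6B", "plasma", "N", "none", 2, 24.0),
    ])


@pytest.fixture
def csv_text() -> str:
    return (
        "sample_id,assay,specimen,group,timepoint,replicate,ct\n"
        "s1,miR-451,plasma,BC,none,1,30.1\n"
        "s1,miR-451,plasma,BC,none,2,30.3\n"
    )


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
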