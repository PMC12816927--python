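import numpy as np
import pytest

from mrpv.faers import ReportDatabase, ReportRecord
from mrpv.hierarchy import generate_term_hierarchy


@pytest.fixture(scope="session")
def small_hierarchy():
    """2 SOCs x fanout (2,2,2): 16 PTs, plus one SMQ over three of them."""
    h = generate_term_hierarchy(n_soc=2, fanout=(2, 2, 2), seed=0)
    pts = sorted(h.pts())
    h.add_smq("smq_test", narrow=pts[:1], broad=pts[:3])
    return h


@pytest.fixture()
def tiny_records(small_hierarchy):
    pts = sorted(small_hierarchy.pts())
    return [
        ReportRecord(11, 1, 1, [("drugA", "PS")], [pts[0]], sex="F", indication="weight_loss"),
        ReportRecord(12, 1, 2, [("drugA", "PS")], [pts[0], pts[1]], sex="F", indication="weight_loss"),
        ReportRecord(21, 2, 1, [("drugB", "PS"), ("drugA", "C")], [pts[2]], sex="M"),
        ReportRecord(31, 3, 1, [("drugA", "PS")], [pts[3]], sex="M", indication="glucose_lowering"),
        ReportRecord(41, 4, 1, [("drugB", "PS")], [pts[0]], sex="unknown"),
    ]


@pytest.fixture()
def tiny_db(tiny_records):
    return ReportDatabase.from_records(
        tiny_records, drug_classes={"drugA": "classA", "drugB": "classB"}
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
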