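import re

import numpy as np
import pytest

from pepmotifs import PeptideRecord
from pepmotifs.motifs import MotifPattern


def regex_starts(sequence: str, pattern: MotifPattern) -> list[int]:
    """Independent occurrence oracle: regex with a lookahead so overlapping
    matches are all reported."""
    parts = []
    for i, cls in enumerate(pattern.classes):
        if i:
            parts.append("." * pattern.gaps[i - 1])
        parts.append("[" + "".join(sorted(cls)) + "]")
    rx = re.compile("(?=" + "".join(parts) + ")")
    return [m.start() for m in rx.finditer(sequence)]


def bh_stepup(pvalues) -> np.ndarray:
    """Independent Benjamini–Hochberg oracle: adj_i = min_{j>=i}(m * p_(j) / j),
    computed directly from the step-up formula."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def make_records(sequences, seq_type="cTP", lineage=(), prefix="r"):
    return [
        PeptideRecord(id=f"{prefix}{i}", sequence=s, seq_type=seq_type, lineage=lineage)
        for i, s in enumerate(sequences)
    ]


@pytest.fixture
def toy_records():
    return make_records(["MASSLRAQGT", "LLLLKKKKRR", "SASASASAQQ"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
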