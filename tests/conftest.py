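import numpy as np
import pytest

from phylowave.seqcore import GroupedAlignment, Sequence


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_alignment(rows: dict[str, str], labels: dict[str, str],
                   order: list[str] | None = None) -> GroupedAlignment:
    seqs = [Sequence(id=k, residues=v) for k, v in rows.items()]
    return GroupedAlignment(seqs, labels, order or [])


@pytest.fixture
def tiny_grouped_alignment() -> GroupedAlignment:
    """Two groups of three sequences over five columns."""
    rows = {
        "a1": "DAACD",
        "a2": "DAACD",
        "a3": "DAGCD",
        "b1": "RAACD",
        "b2": "RATCD",
        "b3": "RAACD",
    }
    labels = {k: ("g1" if k.startswith("a") else "g2") for k in rows}
    return make_alignment(rows, labels, ["g1", "g2"])
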