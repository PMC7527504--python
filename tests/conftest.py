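import pytest

from sfbkit import Alignment, SequenceRecord
from sfbkit.simulate import fixture_worked_examples


def make_alignment(seqs, kind="nucleotide", prefix="s"):
    return Alignment(
        tuple(SequenceRecord(f"{prefix}{i + 1}", s) for i, s in enumerate(seqs)),
        kind=kind,
    )


@pytest.fixture(scope="session")
def worked_examples():
    return fixture_worked_examples()
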