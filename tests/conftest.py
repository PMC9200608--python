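import pytest
from hypothesis import settings

from hashdedup import SequenceRecord

settings.register_profile("deterministic", derandomize=True,
                          max_examples=50, deadline=None)
settings.load_profile("deterministic")

# Five-read nucleotide corpus mirroring the classic walkthrough: read 3 is
# an exact copy of read 1, read 4 is the reverse complement of read 2, and
# read 5 is unrelated to everything (including reverse complements).
WORKED_EXAMPLE_SEQS = [
    "AAAACCCC",   # R1
    "ACGTACTG",   # R2
    "AAAACCCC",   # R3 == R1 (exact duplicate)
    "CAGTACGT",   # R4 == reverse complement of R2
    "GGTTAACC",   # R5 unrelated
]


@pytest.fixture
def worked_example_records() -> list[SequenceRecord]:
    return [
        SequenceRecord(identifier=f"R{i + 1}", sequence=seq,
                       quality="I" * len(seq), ordinal=i)
        for i, seq in enumerate(WORKED_EXAMPLE_SEQS)
    ]
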