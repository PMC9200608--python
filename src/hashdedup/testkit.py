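"""Synthetic read corpora with planted duplicates, and a hash-free oracle.

The generator emulates the duplicate structure of real sequencing libraries
at known, controllable rates: exact PCR-style copies, copies read from the
opposite strand (reverse complements), and — for paired layouts — pairs
whose mates reappear swapped.  Every fixture carries its own ground truth,
so engine output can be checked ordinal-for-ordinal.

The oracle is a deliberate second implementation of the duplicate relation:
quadratic, string-comparison only, no hashing, with its own complement
table.  Engine/oracle disagreement on a collision-free corpus indicates a
bug; agreement is what the acceptance checks assert.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .dedup_engine import DedupOptions, PAIRED, SINGLE
from .errors import GenerationError
from .seqio import RecordPair, SequenceRecord

# Independent complement table -- maps plain bases only, which is all the
# generator emits.  Kept separate from sequence_ops on purpose.
_ORACLE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_NT_BASES = "ACGT"
_AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"
_PHRED_CHARS = "".join(chr(33 + q) for q in range(2, 41))

LABEL_TEMPLATE = "template"
LABEL_EXACT = "exact"
LABEL_RC = "rc"
LABEL_SWAP = "swap"


def _oracle_rc(seq: str) -> str:
    return "".join(_ORACLE_COMPLEMENT[b] for b in reversed(seq))


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic corpus.

    Rates are fractions of ``n_templates``: ``exact_dup_rate=0.2`` with 100
    templates plants 20 exact copies, giving 120 reads of which 100 are
    unique.  ``rc_dup_rate`` requires the nucleotide alphabet and
    ``swap_rate`` the paired layout.
    """

    n_templates: int = 100
    read_length: int = 80
    exact_dup_rate: float = 0.0
    rc_dup_rate: float = 0.0
    swap_rate: float = 0.0
    alphabet: str = "nucleotide"
    paired: bool = False
    shuffle: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exact_dup_rate", "rc_dup_rate", "swap_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {rate}")
        if self.n_templates < 1:
            raise GenerationError("n_templates must be positive")
        if self.read_length < 1:
            raise GenerationError("read_length must be positive")
        if self.rc_dup_rate > 0 and self.alphabet != "nucleotide":
            raise GenerationError(
                "reverse-complement duplicates require nucleotides")
        if self.swap_rate > 0 and not self.paired:
            raise GenerationError("swapped duplicates require paired layout")


@dataclass
class GroundTruth:
    """Per-ordinal labels plus the duplicate relation, both ways.

    ``labels[i]`` says how read/pair ``i`` was planted.  ``keys_exact`` and
    ``keys_rc`` hold the equivalence key of each ordinal under the
    strict-strand and strand-collapsed relations respectively; the kept set
    for a relation is the first occurrence of each key.
    """

    labels: list[str]
    keys_exact: list[object]
    keys_rc: list[object]

    def kept_ordinals(self, rc_enabled: bool) -> list[int]:
        keys = self.keys_rc if rc_enabled else self.keys_exact
        seen: set[object] = set()
        kept = []
        for i, key in enumerate(keys):
            if key not in seen:
                seen.add(key)
                kept.append(i)
        return kept

    def duplicate_ordinals(self, rc_enabled: bool) -> list[int]:
        kept = set(self.kept_ordinals(rc_enabled))
        return [i for i in range(len(self.labels)) if i not in kept]

    def expected_unique(self, rc_enabled: bool) -> int:
        keys = self.keys_rc if rc_enabled else self.keys_exact
        return len(set(keys))


def _random_quality(rng: random.Random, length: int) -> str:
    return "".join(rng.choices(_PHRED_CHARS, k=length))


def _distinct_templates(rng: random.Random, spec: FixtureSpec,
                        count: int) -> list[str]:
    letters = _NT_BASES if spec.alphabet == "nucleotide" else _AA_LETTERS
    if len(letters) ** spec.read_length < 2 * count:
        raise GenerationError(
            f"alphabet of {len(letters)} letters at length "
            f"{spec.read_length} cannot yield {count} distinct templates")
    templates: list[str] = []
    taken: set[str] = set()
    attempts = 0
    while len(templates) < count:
        attempts += 1
        if attempts > 100 * count + 1000:
            raise GenerationError("could not draw distinct templates")
        seq = "".join(rng.choices(letters, k=spec.read_length))
        # Templates must be distinct from each other AND from each other's
        # reverse complements, so planted labels stay unambiguous.
        if spec.alphabet == "nucleotide":
            rc = _oracle_rc(seq)
            if seq in taken or rc in taken or seq == rc:
                continue
            taken.add(seq)
            taken.add(rc)
        else:
            if seq in taken:
                continue
            taken.add(seq)
        templates.append(seq)
    return templates


def generate_fixture(
    spec: FixtureSpec,
) -> tuple[list[SequenceRecord] | list[RecordPair], GroundTruth]:
    """Build a corpus per ``spec``; fully reproducible from ``spec.seed``.

    Templates come first, then planted duplicates each copying a random
    earlier template; an optional shuffle permutes everything, after which
    ground truth is recomputed so first-occurrence labeling stays valid.
    """
    rng = random.Random(spec.seed)
    n_exact = round(spec.exact_dup_rate * spec.n_templates)
    n_rc = round(spec.rc_dup_rate * spec.n_templates)
    n_swap = round(spec.swap_rate * spec.n_templates)

    if spec.paired:
        return _generate_paired(rng, spec, n_exact, n_rc, n_swap)
    return _generate_single(rng, spec, n_exact, n_rc)


def _generate_single(rng: random.Random, spec: FixtureSpec,
                     n_exact: int, n_rc: int):
    templates = _distinct_templates(rng, spec, spec.n_templates)
    seqs = list(templates)
    labels = [LABEL_TEMPLATE] * spec.n_templates
    for _ in range(n_exact):
        seqs.append(rng.choice(templates))
        labels.append(LABEL_EXACT)
    for _ in range(n_rc):
        seqs.append(_oracle_rc(rng.choice(templates)))
        labels.append(LABEL_RC)

    order = list(range(len(seqs)))
    if spec.shuffle:
        rng.shuffle(order)
    seqs = [seqs[i] for i in order]
    labels = [labels[i] for i in order]

    records = [
        SequenceRecord(identifier=f"read{i}", sequence=seq,
                       quality=_random_quality(rng, len(seq)), ordinal=i)
        for i, seq in enumerate(seqs)
    ]
    truth = GroundTruth(
        labels=labels,
        keys_exact=list(seqs),
        keys_rc=[min(s, _oracle_rc(s)) if spec.alphabet == "nucleotide"
                 else s for s in seqs],
    )
    return records, truth


def _generate_paired(rng: random.Random, spec: FixtureSpec,
                     n_exact: int, n_rc: int, n_swap: int):
    # 2*n_templates distinct sequences -> n_templates distinct mate pairs.
    flat = _distinct_templates(rng, spec, 2 * spec.n_templates)
    template_pairs = [(flat[2 * i], flat[2 * i + 1])
                      for i in range(spec.n_templates)]
    pairs = list(template_pairs)
    labels = [LABEL_TEMPLATE] * spec.n_templates
    for _ in range(n_exact):
        pairs.append(rng.choice(template_pairs))
        labels.append(LABEL_EXACT)
    for _ in range(n_rc):
        m1, m2 = rng.choice(template_pairs)
        pairs.append((_oracle_rc(m1), _oracle_rc(m2)))
        labels.append(LABEL_RC)
    for _ in range(n_swap):
        m1, m2 = rng.choice(template_pairs)
        pairs.append((m2, m1))
        labels.append(LABEL_SWAP)

    order = list(range(len(pairs)))
    if spec.shuffle:
        rng.shuffle(order)
    pairs = [pairs[i] for i in order]
    labels = [labels[i] for i in order]

    record_pairs = []
    for i, (m1, m2) in enumerate(pairs):
        record_pairs.append(RecordPair(
            SequenceRecord(identifier=f"pair{i}/1", sequence=m1,
                           quality=_random_quality(rng, len(m1)), ordinal=i),
            SequenceRecord(identifier=f"pair{i}/2", sequence=m2,
                           quality=_random_quality(rng, len(m2)), ordinal=i),
            ordinal=i,
        ))
    keys_rc = []
    for m1, m2 in pairs:
        if spec.alphabet == "nucleotide":
            keys_rc.append(min(tuple(sorted((m1, m2))),
                               tuple(sorted((_oracle_rc(m1),
                                             _oracle_rc(m2))))))
        else:
            keys_rc.append(tuple(sorted((m1, m2))))
    truth = GroundTruth(
        labels=labels,
        keys_exact=[(m1, m2) for m1, m2 in pairs],
        keys_rc=keys_rc,
    )
    return record_pairs, truth


def oracle_dedup(items, opts: DedupOptions) -> list[int]:
    """Ground-truth kept ordinals by exhaustive string comparison.

    No hashing anywhere: each read (or pair) is compared against every
    earlier *kept* read.  Single-end with reverse-complement matching on, a
    read is a duplicate if it equals an earlier kept read or that read's
    reverse complement.  Paired-end without the option compares ordered
    mates; with it, the unordered mate multiset is compared directly and
    after reverse-complementing both mates.  The first occurrence of every
    class is always kept.
    """
    if opts.mode == SINGLE:
        return _oracle_single(items, opts.rc_enabled)
    if opts.mode == PAIRED:
        return _oracle_paired(items, opts.rc_enabled)
    raise ValueError(f"unknown mode {opts.mode!r}")


def _oracle_single(records, rc_enabled: bool) -> list[int]:
    kept: list[int] = []
    kept_seqs: list[str] = []
    for i, rec in enumerate(records):
        seq = rec.sequence if isinstance(rec, SequenceRecord) else rec
        rc = _oracle_rc(seq) if rc_enabled else None
        # list membership is a linear scan of string equality -- no hashing
        dup = seq in kept_seqs or (rc is not None and rc in kept_seqs)
        if not dup:
            kept.append(i)
            kept_seqs.append(seq)
    return kept


def _oracle_paired(pairs, rc_enabled: bool) -> list[int]:
    kept: list[int] = []
    kept_keys: list[tuple[str, ...]] = []
    for i, pair in enumerate(pairs):
        if isinstance(pair, RecordPair):
            m1, m2 = pair.mate1.sequence, pair.mate2.sequence
        else:
            m1, m2 = pair
        if rc_enabled:
            probe = tuple(sorted((m1, m2)))
            probe_rc = tuple(sorted((_oracle_rc(m1), _oracle_rc(m2))))
            dup = probe in kept_keys or probe_rc in kept_keys
            key = probe
        else:
            key = (m1, m2)
            dup = key in kept_keys
        if not dup:
            kept.append(i)
            kept_keys.append(key)
    return kept
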