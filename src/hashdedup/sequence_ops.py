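"""Sequence normalization, reverse complementation, and hashing.

Every read (or read pair) is reduced to one unsigned 64-bit integer before
duplicate membership is tested, so the whole deduplication state is a set of
machine-width integers rather than the read text itself.  The digest here is
seedable and process-independent: the same residues and seed always yield the
same value, on any platform.

Three hash constructions are exposed:

``hash_sequence``
    digest of a single normalized read.
``pair_hash_concat``
    order-sensitive digest of a mate pair, used when reverse-complement
    matching is off.  A separator byte is inserted between the mates so that
    pairs like ``("ACGTA", "C")`` and ``("ACGT", "AC")`` cannot collide by
    construction.
``pair_hash_sum``
    sum of the two mates' digests modulo 2**64, used when reverse-complement
    matching is on.  Addition is commutative, so a pair whose mates appear
    swapped at a later file position maps to the same value and is removed
    as a duplicate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .errors import InvalidCharacterError, MalformedRecordError, \
    UnsupportedOperationError

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"

#: IUPAC nucleotide codes accepted after normalization (U has become T).
NUCLEOTIDE_ALPHABET = frozenset("ACGTNRYSWKMBDHV")

#: The 20 amino acids plus ambiguity codes B, Z, X and the stop symbol.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" "BZX*")

# Watson-Crick complement extended over the IUPAC ambiguity codes.
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: Byte placed between mates in the concatenation hash; deliberately outside
#: both residue alphabets so mate boundaries cannot be forged.
PAIR_SEPARATOR = "+"

_MASK64 = (1 << 64) - 1


@dataclass(frozen=True)
class HashConfig:
    """Parameters of the digest, fixed for the lifetime of one run.

    seed
        folded into the digest; two runs with equal seeds produce equal hash
        values for equal sequences.  Default 0 keeps runs reproducible
        across processes.
    width_bits
        digest width; fixed at 64.
    """

    seed: int = 0
    width_bits: int = 64

    def __post_init__(self) -> None:
        if self.width_bits != 64:
            raise ValueError("only 64-bit digests are supported")
        if not 0 <= self.seed < (1 << 64):
            raise ValueError("seed must be an unsigned 64-bit integer")

    @property
    def _salt(self) -> bytes:
        return self.seed.to_bytes(8, "little")


DEFAULT_HASH_CONFIG = HashConfig()


def normalize_sequence(raw: str, alphabet: str = NUCLEOTIDE, *,
                       record: str | None = None,
                       ordinal: int | None = None) -> str:
    """Uppercase ``raw`` and validate it against ``alphabet``.

    In nucleotide mode every U (RNA) is rewritten to T so the reverse
    complement is well defined.  Characters outside the alphabet raise
    :class:`InvalidCharacterError` naming the record and the character;
    empty input raises :class:`MalformedRecordError`.
    """
    if not raw:
        raise MalformedRecordError(
            f"empty sequence{f' in record {record!r}' if record else ''}",
            ordinal=ordinal)
    seq = raw.upper()
    if alphabet == NUCLEOTIDE:
        seq = seq.replace("U", "T")
        allowed = NUCLEOTIDE_ALPHABET
    elif alphabet == PROTEIN:
        allowed = PROTEIN_ALPHABET
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    for ch in set(seq) - allowed:
        raise InvalidCharacterError(ch, record=record, ordinal=ordinal)
    return seq


def reverse_complement(seq: str, alphabet: str = NUCLEOTIDE) -> str:
    """Reverse complement of a normalized nucleotide sequence.

    Ambiguity codes follow the standard IUPAC complement table (R<->Y,
    K<->M, B<->V, D<->H; N, S, W are self-complementary).  The operation is
    an involution.  Calling it in protein mode is an error: amino-acid
    sequences have no complement.
    """
    if alphabet != NUCLEOTIDE:
        raise UnsupportedOperationError(
            "reverse complement is undefined for protein sequences")
    return seq.translate(_COMPLEMENT)[::-1]


def hash_sequence(seq: str, cfg: HashConfig = DEFAULT_HASH_CONFIG) -> int:
    """64-bit digest of the residue text.

    Depends only on the residues and the seed -- never on the record
    identifier or quality string.  Implemented as BLAKE2b truncated to
    8 bytes with the seed as salt: fast, seedable, and with a collision
    probability at corpus scale (~1e5 reads) around 2.7e-10.
    """
    h = hashlib.blake2b(seq.encode("ascii"), digest_size=8, salt=cfg._salt)
    return int.from_bytes(h.digest(), "little")


def pair_hash_concat(s1: str, s2: str,
                     cfg: HashConfig = DEFAULT_HASH_CONFIG) -> int:
    """Order-sensitive pair digest: hash of ``s1 + '+' + s2``.

    The separator sits outside both residue alphabets, so distinct mate
    splits of the same concatenated text hash differently.
    """
    return hash_sequence(s1 + PAIR_SEPARATOR + s2, cfg)


def pair_hash_sum(s1: str, s2: str,
                  cfg: HashConfig = DEFAULT_HASH_CONFIG) -> int:
    """Commutative pair digest: mate digests summed modulo 2**64.

    ``pair_hash_sum(a, b) == pair_hash_sum(b, a)`` for all inputs, which is
    what makes swapped mate pairs detectable as duplicates.
    """
    return (hash_sequence(s1, cfg) + hash_sequence(s2, cfg)) & _MASK64
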