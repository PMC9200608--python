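# Methods

## The deduplication model

`hashdedup` treats two single-end reads as duplicates when their residue
sequences are identical after normalization (uppercasing, U→T), and —
when reverse-complement matching is enabled — also when one equals the
reverse complement of the other. For paired-end data the unit is the mate
pair: without reverse-complement matching two pairs are duplicates only
if mate 1 equals mate 1 and mate 2 equals mate 2 (order-sensitive); with
it, pairs are compared as unordered mate multisets, directly and after
reverse-complementing both mates, so swapped pairs and opposite-strand
pairs collapse. Quality strings and identifiers never participate: the
first occurrence of a class is emitted verbatim and all later members are
discarded. This is exact-duplicate removal only — no mismatch tolerance,
no quality-aware representative selection, no reference alignment.

The implementation realizes this relation with a streaming hash-set
membership test. Every read maps to a 64-bit digest; a set holds the
digests of reads declared unique; classification is a set lookup. The
reverse-complement digest is computed lazily, only after the primary
digest misses, so runs without the option — and all primary-hit reads
with it — never pay for complementation. Only the primary digest of
unique reads is inserted, which gives the memory bound
|set| = unique reads ≤ total reads, exactly.

## Hashing

The digest is BLAKE2b truncated to 8 bytes with the run seed as salt
(`hashlib.blake2b(seq, digest_size=8, salt=seed)`). It is deterministic
across processes and platforms for a fixed seed (default 0, CLI flag
`--seed`), which makes repeated runs byte-identical — a property a
per-process salted hash cannot offer. The choice of a keyed cryptographic
primitive is incidental: any seedable 64-bit digest with uniform output
would do, and the stdlib provides this one at C speed with no extra
dependency.

Collision semantics are inherited from the method, not patched over: two
distinct sequences with equal digests cause the later read to be
silently discarded as a false duplicate. At 64 bits the birthday bound
gives ≈ n²/2⁶⁵ for the probability of any collision among n distinct
reads: 2.7 × 10⁻¹⁰ at n = 10⁵, 2.7 × 10⁻⁶ at n = 10⁷. The paired sum
construction adds the analogous hazard of two distinct pairs with equal
digest sums; its probability is of the same order. The test suite asserts
zero collisions on all its corpora by exhaustive string comparison.

Two constructions reduce a pair to one integer. The concatenation digest
inserts a `+` byte between the mates — a symbol outside both residue
alphabets — so distinct mate splits of the same concatenated text (e.g.
`("ACGTA", "C")` vs `("ACGT", "AC")`) cannot collide structurally. The
sum construction wraps modulo 2⁶⁴ to keep the value fixed-width;
commutativity of addition is precisely what detects swapped (and
swapped-and-complemented) pairs. A deliberate consequence: with
reverse-complement matching ON, mate order is ignored, so `(A, B)`
followed by `(B, A)` is a duplicate; with it OFF the two are distinct.

## Alphabets and normalization

Nucleotide mode accepts the IUPAC codes `ACGTN RYSWKM BDHV` (and U,
normalized to T); the complement table is the standard IUPAC one
(A↔T, C↔G, R↔Y, K↔M, B↔V, D↔H; N, S, W self-complementary), and
reverse complementation is an involution on every valid sequence.
Protein mode accepts the 20 amino-acid letters plus `B`, `Z`, `X` and
`*`; reverse complementation is an error there, and the CLI rejects
`--rc --alphabet aa` before reading any input. Characters outside the
declared alphabet are a hard error naming the record and the character —
not passed through — because a silently hashed invalid byte would create
spurious uniqueness.

## I/O contract

FASTQ is read strictly as 4-line records (the universal modern dialect;
multi-line FASTQ is rejected as malformed, with the record ordinal in the
error). FASTA sequences may span lines; output wraps at 60 columns.
Gzip is detected by magic bytes, the format by the first non-blank
character. Output compression follows the input unless overridden
(`--gzip-output yes|no`). Gzip output is written with fixed mtime and no
embedded filename so repeated runs are byte-identical. The CLI writes to
a temporary file and renames on success, so a failing run leaves no
partial output. Paired output files receive surviving pairs in identical
order, one record at a time, preserving mate synchronization; a
mate-count mismatch between the two inputs raises a synchronization
error naming the surviving file and pair ordinal.

## Synthetic corpora and the oracle

`testkit.generate_fixture` emulates the duplicate structure of real
libraries: distinct random templates (drawn uniformly over plain bases,
pairwise distinct and distinct from each other's reverse complements)
plus planted exact copies, reverse-complement copies, and — for paired
layouts — swapped-mate copies, each copying a random earlier template, at
caller-chosen rates. An optional shuffle permutes the corpus and ground
truth is recomputed so first-occurrence labeling stays valid. Everything
is reproducible from the fixture seed. What it does *not* emulate:
sequencing errors (so no near-duplicates), realistic quality profiles,
length variation, or optical-duplicate spatial structure. Passing tests
therefore certify the exact-duplicate relation and the streaming
mechanics, not robustness to error-containing duplicates — which the
method, by design, does not detect.

`testkit.oracle_dedup` is a second, independent implementation of the
duplicate relation: quadratic, hash-free (linear scans of string
comparisons), with its own complement table. Engine/oracle agreement is
asserted ordinal-for-ordinal across a grid of fixtures spanning mode ×
reverse-complement setting × format × compression × duplicate rate ×
shuffle (256 small fixtures of 40 templates each, plus one corpus of
10,080 single-end reads and one of 5,040 pairs — sizes chosen to keep the
default suite minutes-scale while exercising 10⁴-read inputs). Any
additive-sum collision in the paired engine would surface as an oracle
disagreement rather than being absorbed.

## Numerical and design choices

- Seed default 0; any unsigned 64-bit value is accepted.
- Sum digests wrap modulo 2⁶⁴; all hash values live in [0, 2⁶⁴).
- Empty input streams are valid and produce empty output with zero
  counters; an empty *sequence* is a malformed record.
- Degenerate palindromic reads (r = rc(r)) need no special casing: the
  primary hash handles them, and the fixture generator simply never
  draws palindromes as templates so planted labels stay unambiguous.
- The engine is deliberately sequential and single-pass: determinism is
  part of the contract, and the conserved counters
  (`total_in == unique_out + duplicates_removed`,
  `rc_matched ≤ duplicates_removed`, set cardinality == `unique_out`)
  are checked on every test corpus.

## Known limitations

- A 64-bit collision silently discards a non-duplicate read (see above);
  there is no verification pass against the residues.
- Near-duplicates differing by even one base (sequencing errors) are not
  detected.
- Paired mode requires two synchronized files; interleaved FASTQ and
  SAM/BAM input are out of scope.
- Memory grows with the number of *unique* reads (one 64-bit integer
  each, plus set overhead); corpora with hundreds of millions of unique
  reads need a machine sized accordingly.
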