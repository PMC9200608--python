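# hashdedup

Reference-free (de novo) duplicate-read removal for high-throughput
sequencing data. Duplicate reads — artifacts of PCR amplification or
redundant sequencing — inflate dataset size and bias downstream analyses
such as assembly and abundance estimation. `hashdedup` removes them in a
single streaming pass without aligning to a reference genome, on FASTQ or
FASTA input (plain or gzip), single-end or paired-end, nucleotide or
amino-acid sequences.

## Method

Each read *r* is reduced to a 64-bit integer *h(r)* (a seeded digest of
its normalized residues — uppercased, U→T). The engine keeps a set *S* of
the hashes of reads declared unique so far and streams the input once:

- **single-end.** If *h(r)* ∈ *S* the read is a duplicate and is
  discarded. Otherwise, with reverse-complement matching off, *h(r)* is
  added to *S* and the read is written. With it on, the hash of the
  reverse complement *h(rc(r))* is computed — only now, never on a hit —
  and looked up: a hit discards the read, a miss writes it and inserts
  *h(r)* (and only *h(r)*) into *S*.
- **paired-end.** Each mate pair (*r₁*, *r₂*) is reduced to one integer:
  with reverse-complement matching off the order-sensitive digest
  *h(r₁ ‖ '+' ‖ r₂)*; with it on the commutative sum
  *(h(r₁) + h(r₂)) mod 2⁶⁴*, so a pair whose mates reappear swapped later
  in the files maps to the same value and is removed. On a miss the sum of
  the reverse-complemented mates' hashes is checked before the pair is
  declared unique.

Because only one hash per unique read (or pair) is ever stored,
|*S*| ≤ number of reads, and memory is one integer per surviving read.
The first occurrence of every duplicate class is kept verbatim;
identifiers and quality strings never influence the comparison. Two
distinct reads sharing a hash value (probability ≈ 2.7 × 10⁻¹⁰ for 10⁵
reads at 64 bits) would silently discard a non-duplicate read; this is an
accepted property of the method.

## Worked example

Five reads where read 3 equals read 1 and read 4 is the reverse
complement of read 2:

```sh
$ hashdedup single -i example.fastq -o dedup.fastq --rc --report report.json
INFO reads in: 5, unique out: 3, duplicates removed: 2 (1 via reverse complement)
```

`dedup.fastq` holds reads 1, 2 and 5: read 3 was removed as an exact
duplicate, read 4 only because `--rc` collapses a read with its reverse
complement. Without `--rc` the same command keeps 4 reads (read 4
survives). `report.json` echoes the options and the conserved counters
(`total_in == unique_out + duplicates_removed`), e.g.:

```json
{"duplicates_removed": 2, "rc_matched": 1, "total_in": 5, "unique_out": 3,
 "uniqset_cardinality": 3, ...}
```

Paired-end usage:

```sh
hashdedup paired -1 in_1.fq.gz -2 in_2.fq.gz \
    --out1 out_1.fq.gz --out2 out_2.fq.gz --rc
```

The library API mirrors the CLI: `dedup_single` / `dedup_paired` consume
record streams from `read_records` / `read_pairs` and return the
surviving stream plus live statistics. `hashdedup.testkit` generates
synthetic corpora with planted duplicates at known rates together with a
brute-force, hash-free oracle of the duplicate relation.

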