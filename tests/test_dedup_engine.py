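import pytest

from hashdedup import (
    ConfigurationError,
    DedupOptions,
    InvalidCharacterError,
    RecordPair,
    SequenceRecord,
    UniqSet,
    classify_pair,
    classify_single,
    dedup_paired,
    dedup_single,
    generate_fixture,
    reverse_complement,
)
from helpers import dedup_in_memory, paired_spec, single_spec


def _records(seqs):
    return [SequenceRecord(f"r{i}", s, quality="I" * len(s), ordinal=i)
            for i, s in enumerate(seqs)]


def _pairs(mate_tuples):
    out = []
    for i, (a, b) in enumerate(mate_tuples):
        out.append(RecordPair(
            SequenceRecord(f"p{i}/1", a, quality="I" * len(a), ordinal=i),
            SequenceRecord(f"p{i}/2", b, quality="I" * len(b), ordinal=i),
            ordinal=i))
    return out


SINGLE_RC = DedupOptions(mode="single", rc_enabled=True)
SINGLE_NORC = DedupOptions(mode="single", rc_enabled=False)
PAIRED_RC = DedupOptions(mode="paired", rc_enabled=True)
PAIRED_NORC = DedupOptions(mode="paired", rc_enabled=False)


class TestClassifySingle:
    def test_repeat_is_duplicate_and_set_unchanged(self):
        uniq = UniqSet()
        assert classify_single("AACCGGTA", uniq, SINGLE_NORC).verdict \
            == "unique"
        d = classify_single("AACCGGTA", uniq, SINGLE_NORC)
        assert d.verdict == "duplicate" and not d.via_rc
        assert uniq.cardinality == 1

    def test_rc_duplicate_detected_via_rc(self):
        uniq = UniqSet()
        classify_single("AAACGTTG", uniq, SINGLE_RC)
        d = classify_single(reverse_complement("AAACGTTG"), uniq, SINGLE_RC)
        assert d.verdict == "duplicate"
        assert d.via_rc

    def test_unique_read_inserts_only_primary_hash(self):
        uniq = UniqSet()
        d = classify_single("AAACGTTG", uniq, SINGLE_RC)
        assert d.verdict == "unique"
        assert uniq.cardinality == 1  # the rc hash was NOT inserted
        # the same read again is a plain duplicate (primary hash hit),
        # so its rc hash is never even computed
        d2 = classify_single("AAACGTTG", uniq, SINGLE_RC)
        assert d2.verdict == "duplicate"
        assert not d2.rc_hash_computed

    def test_rc_hash_skipped_when_option_off(self):
        uniq = UniqSet()
        d = classify_single("AAACGTTG", uniq, SINGLE_NORC)
        assert not d.rc_hash_computed


class TestDedupSingle:
    def test_worked_example_rc_off(self, worked_example_records):
        kept, stats = dedup_in_memory(worked_example_records, SINGLE_NORC)
        assert [r.identifier for r in kept] == ["R1", "R2", "R4", "R5"]
        assert stats.duplicates_removed == 1
        assert stats.rc_matched == 0

    def test_worked_example_rc_on(self, worked_example_records):
        kept, stats = dedup_in_memory(worked_example_records, SINGLE_RC)
        assert [r.identifier for r in kept] == ["R1", "R2", "R5"]
        assert stats.duplicates_removed == 2
        assert stats.rc_matched == 1

    def test_empty_stream(self):
        kept, stats = dedup_in_memory([], SINGLE_RC)
        assert kept == []
        assert stats.as_dict() == {k: 0 for k in stats.as_dict()}

    def test_first_occurrence_kept_verbatim(self):
        records = [
            SequenceRecord("first", "ACGTTT", quality="IIIIII", ordinal=0),
            SequenceRecord("second", "ACGTTT", quality="??????", ordinal=1),
        ]
        kept, _ = dedup_in_memory(records, SINGLE_NORC)
        assert len(kept) == 1
        assert kept[0].identifier == "first"
        assert kept[0].quality == "IIIIII"

    def test_case_and_rna_fold_into_duplicates(self):
        # normalization: lowercase and U-for-T spellings are duplicates
        kept, _ = dedup_in_memory(_records(["ACGT", "acgt", "ACGU"]),
                                  SINGLE_NORC)
        assert [r.ordinal for r in kept] == [0]

    def test_invalid_character_cites_ordinal(self):
        stream, _ = dedup_single(_records(["ACGT", "ACXJ"]), SINGLE_NORC)
        with pytest.raises(InvalidCharacterError) as exc:
            list(stream)
        assert exc.value.ordinal == 1

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            dedup_single([], PAIRED_NORC)
        with pytest.raises(ConfigurationError):
            dedup_paired([], SINGLE_NORC)

    def test_protein_mode_dedup(self):
        opts = DedupOptions(mode="single", alphabet="protein")
        kept, stats = dedup_in_memory(_records(["MKVL", "MKVL", "MKVA"]),
                                      opts)
        assert [r.ordinal for r in kept] == [0, 2]
        assert stats.rc_hashes_computed == 0

    def test_rc_with_protein_is_config_error(self):
        with pytest.raises(ConfigurationError):
            DedupOptions(mode="single", rc_enabled=True, alphabet="protein")


class TestClassifyPair:
    def test_swapped_pair_same_sum_hash(self):
        uniq = UniqSet()
        classify_pair("AAAC", "GGGT", uniq, PAIRED_RC)
        d = classify_pair("GGGT", "AAAC", uniq, PAIRED_RC)
        assert d.verdict == "duplicate"

    def test_swapped_pair_distinct_concat_hash(self):
        uniq = UniqSet()
        classify_pair("AAAC", "GGGT", uniq, PAIRED_NORC)
        d = classify_pair("GGGT", "AAAC", uniq, PAIRED_NORC)
        assert d.verdict == "unique"
        assert uniq.cardinality == 2


class TestDedupPaired:
    def test_identical_pair_removed_either_setting(self):
        pairs = _pairs([("AAAC", "GGGT"), ("AAAC", "GGGT")])
        for opts in (PAIRED_NORC, PAIRED_RC):
            kept, stats = dedup_in_memory(pairs, opts)
            assert [p.ordinal for p in kept] == [0]
            assert stats.duplicates_removed == 1

    def test_swapped_pair_duplicate_only_with_rc(self):
        pairs = _pairs([("AAAC", "GGGT"), ("GGGT", "AAAC")])
        kept_rc, _ = dedup_in_memory(pairs, PAIRED_RC)
        assert [p.ordinal for p in kept_rc] == [0]
        kept_norc, _ = dedup_in_memory(pairs, PAIRED_NORC)
        assert [p.ordinal for p in kept_norc] == [0, 1]

    def test_reverse_complemented_pair_duplicate_with_rc(self):
        a, b = "AAACGT", "GGGTAC"
        pairs = _pairs([(a, b),
                        (reverse_complement(a), reverse_complement(b))])
        kept, stats = dedup_in_memory(pairs, PAIRED_RC)
        assert [p.ordinal for p in kept] == [0]
        assert stats.rc_matched == 1

    def test_swapped_and_complemented_pair_duplicate_with_rc(self):
        # commutativity of the sum makes swap+rc a duplicate too
        a, b = "AAACGT", "GGGTAC"
        pairs = _pairs([(a, b),
                        (reverse_complement(b), reverse_complement(a))])
        kept, _ = dedup_in_memory(pairs, PAIRED_RC)
        assert [p.ordinal for p in kept] == [0]

    def test_each_pair_adds_at_most_one_hash(self):
        pairs, _ = generate_fixture(paired_spec(seed=5, exact_dup_rate=0.2))
        for opts in (PAIRED_NORC, PAIRED_RC):
            kept, stats = dedup_in_memory(pairs, opts)
            assert stats.uniqset_cardinality == stats.unique_out


class TestStatsInvariants:
    @pytest.mark.parametrize("rc", [False, True])
    def test_conservation_and_cardinality(self, rc):
        records, _ = generate_fixture(single_spec(
            seed=11, exact_dup_rate=0.3, rc_dup_rate=0.2))
        opts = DedupOptions(mode="single", rc_enabled=rc)
        kept, stats = dedup_in_memory(records, opts)
        assert stats.total_in == stats.unique_out + stats.duplicates_removed
        assert stats.uniqset_cardinality == stats.unique_out
        assert stats.unique_out <= stats.total_in
        assert stats.rc_matched <= stats.duplicates_removed
        if not rc:
            assert stats.rc_matched == 0
            assert stats.rc_hashes_computed == 0

    def test_lazy_rc_counter_equals_primary_misses(self):
        records, _ = generate_fixture(single_spec(
            seed=12, exact_dup_rate=0.4, rc_dup_rate=0.2))
        kept, stats = dedup_in_memory(
            records, DedupOptions(mode="single", rc_enabled=True))
        # a primary-hash miss is either a unique read or an rc-detected dup
        assert stats.rc_hashes_computed == stats.unique_out \
            + stats.rc_matched

    def test_idempotence(self):
        records, _ = generate_fixture(single_spec(
            seed=13, exact_dup_rate=0.3, rc_dup_rate=0.3, shuffle=True))
        opts = DedupOptions(mode="single", rc_enabled=True)
        kept, _ = dedup_in_memory(records, opts)
        again, stats = dedup_in_memory(kept, opts)
        assert stats.duplicates_removed == 0
        assert [r.ordinal for r in again] == [r.ordinal for r in kept]
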