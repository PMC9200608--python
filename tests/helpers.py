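"""Shared plumbing for the test suite: fixture-to-file round trips."""

from __future__ import annotations

from hashdedup import (
    DedupOptions,
    FixtureSpec,
    RecordPair,
    SequenceRecord,
    dedup_paired,
    dedup_single,
    generate_fixture,
    read_pairs,
    read_records,
    write_pairs,
    write_records,
)


def fixture_to_files(items, tmp_path, fmt: str, compress: bool,
                     prefix: str = "reads"):
    """Write generated records or pairs through seqio; returns path(s)."""
    ext = f".{fmt}" + (".gz" if compress else "")
    if items and isinstance(items[0], RecordPair):
        p1 = str(tmp_path / f"{prefix}_1{ext}")
        p2 = str(tmp_path / f"{prefix}_2{ext}")
        write_pairs(p1, p2, items, fmt, compress=compress)
        return p1, p2
    path = str(tmp_path / f"{prefix}{ext}")
    write_records(path, items, fmt, compress=compress)
    return path


def dedup_from_files(paths, opts: DedupOptions):
    """Run the engine over on-disk input; returns (kept ordinals, stats)."""
    if isinstance(paths, tuple):
        kept, stats = dedup_paired(read_pairs(*paths), opts)
    else:
        kept, stats = dedup_single(read_records(paths), opts)
    ordinals = [item.ordinal for item in kept]
    return ordinals, stats


def dedup_in_memory(items, opts: DedupOptions):
    if items and isinstance(items[0], RecordPair):
        kept, stats = dedup_paired(items, opts)
    else:
        kept, stats = dedup_single(items, opts)
    return list(kept), stats


def single_spec(**kw) -> FixtureSpec:
    kw.setdefault("n_templates", 60)
    kw.setdefault("read_length", 50)
    return FixtureSpec(**kw)


def paired_spec(**kw) -> FixtureSpec:
    kw.setdefault("n_templates", 60)
    kw.setdefault("read_length", 50)
    kw.setdefault("paired", True)
    return FixtureSpec(**kw)
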