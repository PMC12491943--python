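"""Sliding-window fragmentation of source genomes into pseudo-reads.

Contaminant-source (e.g. microbial) genomes are cut into fixed-length windows
— 60 bp with a 10 bp step by default — that act as synthetic sequencing
reads. 60 bp is twice the ~30 bp organism-level specificity floor and matches
typical ancient environmental DNA fragment lengths; the 10 bp step gives a
6-fold overlap so every source base is probed by several reads. Each
pseudo-read carries its taxon label and origin coordinates in its read id.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .records import PseudoRead, SequenceRecord

DEFAULT_WINDOW = 60
DEFAULT_STEP = 10

_ACGT = frozenset("ACGT")


def fragment(
    record: SequenceRecord,
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
    drop_ambiguous: bool = True,
    tail_window: bool = False,
) -> list[PseudoRead]:
    """Cut one contig into sliding windows of length ``w`` at step ``s``.

    Windows start at 0, s, 2s, ... while start + w <= length, so a contig of
    length L >= w yields floor((L - w)/s) + 1 windows before ambiguity
    filtering and contigs shorter than w yield none. Sequences are uppercased
    on emission; with ``drop_ambiguous`` any window containing a base outside
    {A,C,G,T} is discarded. ``tail_window`` adds one extra window anchored at
    L - w when the last regular window does not reach the contig end.

    The taxon label is taken from ``record.organism``.
    """
    if s < 1 or s > w:
        raise ValueError(f"step must satisfy 1 <= s <= w, got s={s}, w={w}")
    seq = record.sequence.upper()
    L = len(seq)
    reads: list[PseudoRead] = []
    if L < w:
        return reads
    starts = list(range(0, L - w + 1, s))
    if tail_window and starts[-1] != L - w:
        starts.append(L - w)
    for start in starts:
        window = seq[start : start + w]
        if drop_ambiguous and not _ACGT.issuperset(window):
            continue
        reads.append(
            PseudoRead(
                taxon_label=record.organism,
                source_contig=record.contig_id,
                source_start=start,
                sequence=window,
            )
        )
    return reads


def fragment_set(
    records: Iterable[SequenceRecord],
    w: int = DEFAULT_WINDOW,
    s: int = DEFAULT_STEP,
    drop_ambiguous: bool = True,
    tail_window: bool = False,
) -> tuple[list[PseudoRead], dict[str, int]]:
    """Fragment a taxon-labelled genome collection.

    Returns the concatenated pseudo-read stream plus emitted read counts per
    taxon (the table behind source-share computations such as the
    cyanobacterial fraction of a full corpus). Duplicate (taxon, contig)
    pairs with differing sequences are rejected.
    """
    seen: dict[tuple[str, str], str] = {}
    reads: list[PseudoRead] = []
    counts: Counter[str] = Counter()
    for record in records:
        if not record.organism:
            raise ValueError(
                f"contig {record.contig_id!r} has no taxon label (organism)"
            )
        key = (record.organism, record.contig_id)
        if key in seen and seen[key] != record.sequence:
            raise ValueError(
                f"duplicate contig {key} with differing sequences"
            )
        seen[key] = record.sequence
        chunk = fragment(
            record, w=w, s=s, drop_ambiguous=drop_ambiguous, tail_window=tail_window
        )
        reads.extend(chunk)
        counts[record.organism] += len(chunk)
    return reads, dict(counts)


def taxon_share(counts: dict[str, int], taxa: str | Sequence[str]) -> float:
    """Fraction of all pseudo-reads contributed by one taxon or a taxon group
    (e.g. every species of one phylum). Multiply by 100 for a percentage."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty pseudo-read count table")
    if isinstance(taxa, str):
        taxa = [taxa]
    return sum(counts.get(t, 0) for t in taxa) / total


def pseudoreads_to_records(reads: Iterable[PseudoRead]) -> list[SequenceRecord]:
    """View pseudo-reads as SequenceRecords (for FASTA emission)."""
    return [
        SequenceRecord(
            contig_id=r.read_id, sequence=r.sequence, organism=r.taxon_label
        )
        for r in reads
    ]
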