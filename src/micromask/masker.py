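"""Masking and sequence extraction over region sets.

Hard masking replaces microbial-like bases with 'N' (a hard break for k-mer
profilers, the primary downstream use); soft masking lowercases them.
`complement` returns the presumed-endogenous partition and `extract_fasta`
pulls region sequences out for composition analyses. Masking never changes
sequence length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .records import Region, SequenceRecord

HARD = "hard"
SOFT = "soft"


@dataclass(frozen=True)
class MaskPolicy:
    mode: str = HARD

    def __post_init__(self) -> None:
        if self.mode not in (HARD, SOFT):
            raise ValueError(f"mask mode must be 'hard' or 'soft', got {self.mode!r}")


def _merged_intervals(
    regions: Sequence[Region], target: Sequence[SequenceRecord]
) -> dict[str, list[tuple[int, int]]]:
    """Sort regions per contig and merge overlaps/bookends (tolerates
    third-party BEDs with overlapping rows); validates bounds."""
    lengths = {r.contig_id: r.length for r in target}
    raw: dict[str, list[tuple[int, int]]] = {c: [] for c in lengths}
    for region in regions:
        if region.contig_id not in lengths:
            raise ValueError(f"region on unknown contig {region.contig_id!r}")
        if region.start < 0 or region.end > lengths[region.contig_id]:
            raise ValueError(
                f"region [{region.start}, {region.end}) out of bounds on "
                f"{region.contig_id!r} (length {lengths[region.contig_id]})"
            )
        raw[region.contig_id].append((region.start, region.end))
    merged: dict[str, list[tuple[int, int]]] = {}
    for contig_id, intervals in raw.items():
        intervals.sort()
        out: list[tuple[int, int]] = []
        for start, end in intervals:
            if out and start <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], end))
            else:
                out.append((start, end))
        merged[contig_id] = out
    return merged


def mask_fasta(
    target: Sequence[SequenceRecord],
    regions: Sequence[Region],
    policy: MaskPolicy | str = HARD,
) -> list[SequenceRecord]:
    """Return copies of the target with exactly the region bases masked.

    Bases outside the regions are byte-identical to the input; per contig the
    number of altered positions equals the merged region span.
    """
    if isinstance(policy, str):
        policy = MaskPolicy(policy)
    merged = _merged_intervals(regions, target)
    out: list[SequenceRecord] = []
    for rec in target:
        seq = rec.sequence
        for start, end in merged[rec.contig_id]:
            block = "N" * (end - start) if policy.mode == HARD else seq[start:end].lower()
            seq = seq[:start] + block + seq[end:]
        out.append(
            SequenceRecord(
                contig_id=rec.contig_id,
                sequence=seq,
                assembly_id=rec.assembly_id,
                organism=rec.organism,
            )
        )
    return out


def complement(
    regions: Sequence[Region], target: Sequence[SequenceRecord]
) -> list[Region]:
    """Intervals covering exactly the unmasked (presumed endogenous) bases:
    per contig, the complement is disjoint from the regions and together they
    tile [0, contig length)."""
    merged = _merged_intervals(regions, target)
    out: list[Region] = []
    for rec in target:
        cursor = 0
        for start, end in merged[rec.contig_id]:
            if start > cursor:
                out.append(Region(rec.contig_id, cursor, start))
            cursor = end
        if cursor < rec.length:
            out.append(Region(rec.contig_id, cursor, rec.length))
    return out


def extract_fasta(
    target: Sequence[SequenceRecord],
    regions: Sequence[Region],
    min_length: int = 0,
) -> list[SequenceRecord]:
    """One record per region, id ``contig:start-end`` (0-based half-open),
    sequence equal to the target substring; regions shorter than
    ``min_length`` are skipped."""
    lengths = {r.contig_id: r.length for r in target}
    seqs = {r.contig_id: r.sequence for r in target}
    out: list[SequenceRecord] = []
    for region in regions:
        if region.contig_id not in lengths:
            raise ValueError(f"region on unknown contig {region.contig_id!r}")
        if region.end > lengths[region.contig_id]:
            raise ValueError(
                f"region [{region.start}, {region.end}) out of bounds on "
                f"{region.contig_id!r}"
            )
        if region.length < min_length:
            continue
        out.append(
            SequenceRecord(
                contig_id=f"{region.contig_id}:{region.start}-{region.end}",
                sequence=seqs[region.contig_id][region.start : region.end],
            )
        )
    return out
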