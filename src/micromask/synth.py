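"""Synthetic fixtures: host assemblies with planted contaminant inserts.

Stands in for real eukaryotic assemblies plus a microbial source collection:
i.i.d.-composition host contigs receive copies of source-genome fragments at
known coordinates (variable length, divergence and copy number), and short
reads can be sampled preferentially from inside or outside the planted
regions. Ground truth travels with the fixture so detection recall/precision,
taxon attribution, multimapper saturation and enrichment calibration are all
measurable without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import AlignmentRecord, Region, SequenceRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def generate_host(
    n_contigs: int,
    lengths: int | Sequence[int],
    gc: float = 0.5,
    seed: int = 0,
    assembly_id: str = "synthetic_host",
) -> list[SequenceRecord]:
    """Host contigs with i.i.d. bases at the given GC fraction."""
    if not 0 < gc < 1:
        raise ValueError(f"gc must be in (0, 1), got {gc}")
    if isinstance(lengths, int):
        lengths = [lengths] * n_contigs
    if len(lengths) != n_contigs or any(l < 1 for l in lengths):
        raise ValueError("need one positive length per contig")
    rng = np.random.default_rng(seed)
    return [
        SequenceRecord(
            contig_id=f"contig_{i + 1}",
            sequence=_random_sequence(rng, length, gc),
            assembly_id=assembly_id,
        )
        for i, length in enumerate(lengths)
    ]


def generate_sources(
    n_taxa: int,
    length: int,
    gc: float = 0.5,
    seed: int = 0,
) -> list[SequenceRecord]:
    """One single-contig source genome per taxon, labels taxon_01, ..."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_taxa):
        taxon = f"taxon_{i + 1:02d}"
        out.append(
            SequenceRecord(
                contig_id=f"{taxon}_c1",
                sequence=_random_sequence(rng, length, gc),
                assembly_id=taxon,
                organism=taxon,
            )
        )
    return out


def mutate(sequence: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base independently at ``rate`` (always to a different
    base); returns the mutated sequence and the substitution count."""
    if rate == 0:
        return sequence, 0
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.flatnonzero(hit)
    lut = {b: [c for c in b"ACGT" if c != b] for b in b"ACGT"}
    for i in idx:
        arr[i] = rng.choice(lut[arr[i]])
    return arr.tobytes().decode("ascii"), len(idx)


@dataclass
class PlantedInsert:
    """One planted copy of a source fragment, in host coordinates."""

    contig_id: str
    start: int
    end: int
    taxon: str
    source_contig: str
    source_start: int
    n_substitutions: int
    divergence: float

    @property
    def region(self) -> Region:
        return Region(self.contig_id, self.start, self.end,
                      taxon_counts={self.taxon: 0})


@dataclass
class SyntheticTruth:
    """A host assembly with planted inserts and their ground truth."""

    host: list[SequenceRecord]
    sources: list[SequenceRecord]
    inserts: list[PlantedInsert]
    seed: int = 0

    @property
    def truth_regions(self) -> list[Region]:
        return sorted(
            (ins.region for ins in self.inserts),
            key=lambda r: (r.contig_id, r.start),
        )


def plant_inserts(
    host: Sequence[SequenceRecord],
    sources: Sequence[SequenceRecord],
    n_inserts: int,
    insert_length: int,
    divergence: float = 0.0,
    copy_number: int = 1,
    seed: int = 0,
    max_attempts: int = 1000,
) -> SyntheticTruth:
    """Copy source fragments into the host at disjoint random positions.

    Each of the ``n_inserts`` fragments is cut from a (cyclically chosen)
    source genome and planted ``copy_number`` times; every planted copy is
    substituted independently at the divergence rate, so multicopy inserts
    diverge from each other at ~2x the per-copy rate. Placement is rejection
    sampling against previously planted intervals.
    """
    if insert_length < 60:
        raise ValueError("insert_length must be >= 60 (the pseudo-read window)")
    if not sources:
        raise ValueError("need at least one source genome")
    rng = np.random.default_rng(seed)
    sequences = {r.contig_id: list(r.sequence) for r in host}
    occupied: dict[str, list[tuple[int, int]]] = {r.contig_id: [] for r in host}
    host_ids = [r.contig_id for r in host]
    host_lengths = {r.contig_id: r.length for r in host}

    inserts: list[PlantedInsert] = []
    for i in range(n_inserts):
        src = sources[i % len(sources)]
        if src.length < insert_length:
            raise ValueError(
                f"source {src.contig_id!r} shorter than insert_length"
            )
        src_start = int(rng.integers(0, src.length - insert_length + 1))
        fragment_seq = src.sequence[src_start : src_start + insert_length]
        for _copy in range(copy_number):
            mutated, n_subs = mutate(fragment_seq, divergence, rng)
            placed = False
            for _attempt in range(max_attempts):
                contig_id = host_ids[int(rng.integers(0, len(host_ids)))]
                if host_lengths[contig_id] < insert_length:
                    continue
                start = int(
                    rng.integers(0, host_lengths[contig_id] - insert_length + 1)
                )
                end = start + insert_length
                if any(start < e and s < end for s, e in occupied[contig_id]):
                    continue
                sequences[contig_id][start:end] = mutated
                occupied[contig_id].append((start, end))
                inserts.append(
                    PlantedInsert(
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        taxon=src.organism,
                        source_contig=src.contig_id,
                        source_start=src_start,
                        n_substitutions=n_subs,
                        divergence=divergence,
                    )
                )
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"could not place insert {i} disjointly after "
                    f"{max_attempts} attempts; host too small"
                )
    new_host = [
        SequenceRecord(
            contig_id=r.contig_id,
            sequence="".join(sequences[r.contig_id]),
            assembly_id=r.assembly_id,
            organism=r.organism,
        )
        for r in host
    ]
    return SyntheticTruth(host=new_host, sources=list(sources),
                          inserts=inserts, seed=seed)


def sample_reads(
    host: Sequence[SequenceRecord],
    regions: Sequence[Region],
    n_reads: int,
    read_length: int = 60,
    inside_fraction: float = 0.0,
    seed: int = 0,
    ct_damage: float = 0.0,
) -> tuple[list[AlignmentRecord], list[SequenceRecord]]:
    """Draw reads from the host, a chosen fraction from region-overlapping
    starts.

    ``inside_fraction`` of the reads start uniformly among the positions
    whose window overlaps >= 1 region base; the rest start uniformly among
    all valid positions. Returns truth placements (forward strand, rank 1)
    plus the read sequences. ``ct_damage`` optionally applies an ancient-DNA
    style terminal substitution (5' C->T, 3' G->A) at the given probability.
    """
    if not 0 <= inside_fraction <= 1:
        raise ValueError("inside_fraction must be in [0, 1]")
    if n_reads == 0:
        return [], []
    usable = [r for r in host if r.length >= read_length]
    if not usable:
        raise ValueError("read_length exceeds every contig")
    if inside_fraction > 0 and not regions:
        raise ValueError("inside_fraction > 0 requires a non-empty region set")
    rng = np.random.default_rng(seed)

    # enumerate starts per contig: all valid, and those overlapping a region
    all_starts: list[tuple[str, int]] = []   # (contig, n_valid) expanded lazily
    inside_starts: list[tuple[str, np.ndarray]] = []
    lengths = {r.contig_id: r.length for r in usable}
    cover = {r.contig_id: np.zeros(r.length, dtype=np.int64) for r in usable}
    for region in regions:
        if region.contig_id in cover:
            cover[region.contig_id][region.start : region.end] = 1
    for rec in usable:
        cum = np.concatenate([[0], np.cumsum(cover[rec.contig_id])])
        starts = np.arange(rec.length - read_length + 1)
        inside = starts[(cum[starts + read_length] - cum[starts]) > 0]
        if inside.size:
            inside_starts.append((rec.contig_id, inside))
        all_starts.append((rec.contig_id, rec.length - read_length + 1))

    n_inside = int(round(inside_fraction * n_reads))
    if n_inside > 0 and not inside_starts:
        raise ValueError("no read start overlaps any region")

    seqs = {r.contig_id: r.sequence.upper() for r in usable}
    placements: list[AlignmentRecord] = []
    reads: list[SequenceRecord] = []

    def emit(contig_id: str, start: int, idx: int) -> None:
        read_id = f"sample_{idx:06d}"
        seq = seqs[contig_id][start : start + read_length]
        if ct_damage > 0:
            s = list(seq)
            if s[0] == "C" and rng.random() < ct_damage:
                s[0] = "T"
            if s[-1] == "G" and rng.random() < ct_damage:
                s[-1] = "A"
            seq = "".join(s)
        placements.append(
            AlignmentRecord(
                read_id=read_id,
                contig_id=contig_id,
                start=start,
                end=start + read_length,
                strand="+",
            )
        )
        reads.append(SequenceRecord(contig_id=read_id, sequence=seq))

    # inside draws: uniform over the pooled overlapping starts
    if n_inside > 0:
        pool_sizes = np.array([s.size for _, s in inside_starts])
        pool_cum = np.cumsum(pool_sizes)
        picks = rng.integers(0, pool_cum[-1], size=n_inside)
        for idx, pick in enumerate(picks):
            which = int(np.searchsorted(pool_cum, pick, side="right"))
            contig_id, pool = inside_starts[which]
            start = int(pool[pick - (pool_cum[which] - pool_sizes[which])])
            emit(contig_id, start, idx)

    # remaining draws: uniform over all valid starts genome-wide
    n_outside = n_reads - n_inside
    if n_outside > 0:
        sizes = np.array([n for _, n in all_starts])
        cum = np.cumsum(sizes)
        picks = rng.integers(0, cum[-1], size=n_outside)
        for j, pick in enumerate(picks):
            which = int(np.searchsorted(cum, pick, side="right"))
            contig_id = all_starts[which][0]
            start = int(pick - (cum[which] - sizes[which]))
            emit(contig_id, start, n_inside + j)

    return placements, reads
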