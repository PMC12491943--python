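"""Coverage-interval calling and region statistics.

Alignments of microbial pseudo-reads are reduced to per-base depth tracks;
maximal runs of depth >= 1 become microbial-like regions (merge distance 0:
adjacent covered bases join, bookended intervals stay separate only across a
zero-depth base). Each region carries its supporting-read count and ranked
taxon attribution, and downstream summaries report breadth of coverage
(fraction of reference bases covered at least once), per-contig
microbial-like fractions, and genome-by-taxon abundance matrices.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import AlignmentRecord, BedRow, Region, SequenceRecord

DEFAULT_TOP_TAXA = 5


@dataclass
class CoverageTrack:
    """Per-base read depth over one contig."""

    contig_id: str
    depth: np.ndarray

    @classmethod
    def from_alignments(
        cls, contig: SequenceRecord, alignments: Iterable[AlignmentRecord]
    ) -> "CoverageTrack":
        # difference-array accumulation; each alignment increments exactly
        # (end - start) bases
        diff = np.zeros(contig.length + 1, dtype=np.int64)
        for a in alignments:
            if a.contig_id != contig.contig_id:
                continue
            if a.start < 0 or a.end > contig.length:
                raise ValueError(
                    f"alignment {a.read_id!r} [{a.start}, {a.end}) exceeds "
                    f"contig {contig.contig_id!r} bounds (length {contig.length})"
                )
            diff[a.start] += 1
            diff[a.end] -= 1
        return cls(contig.contig_id, np.cumsum(diff[:-1]))


def call_regions(
    alignments: Sequence[AlignmentRecord],
    target: Sequence[SequenceRecord],
) -> list[Region]:
    """Merge covered bases into maximal depth >= 1 runs, per contig.

    Every base of an alignment interval is covered, so each alignment falls
    wholly inside exactly one region; NREADS and the taxon counts tally the
    taxon-labelled (pseudo-read) alignments assigned to each region.
    Unlabelled (sample-read) alignments still contribute depth when present
    but never count toward NREADS, per the report's semantics.
    """
    by_contig: dict[str, list[AlignmentRecord]] = {}
    known = {r.contig_id for r in target}
    for a in alignments:
        if a.contig_id not in known:
            raise ValueError(
                f"alignment {a.read_id!r} references unknown contig "
                f"{a.contig_id!r}"
            )
        by_contig.setdefault(a.contig_id, []).append(a)

    regions: list[Region] = []
    for contig in target:
        chunk = by_contig.get(contig.contig_id)
        if not chunk:
            continue
        track = CoverageTrack.from_alignments(contig, chunk)
        covered = track.depth > 0
        # run boundaries from the sign changes of the covered indicator
        edges = np.diff(covered.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if covered[0]:
            starts = np.insert(starts, 0, 0)
        if covered[-1]:
            ends = np.append(ends, contig.length)
        contig_regions = [
            Region(contig.contig_id, int(s), int(e))
            for s, e in zip(starts, ends)
        ]
        # each alignment lies wholly inside one region: locate by start
        region_starts = np.array([r.start for r in contig_regions])
        counters = [Counter() for _ in contig_regions]
        for a in chunk:
            if not a.taxon_label:
                continue
            idx = int(np.searchsorted(region_starts, a.start, side="right")) - 1
            counters[idx][a.taxon_label] += 1
        for region, counter in zip(contig_regions, counters):
            region.taxon_counts = dict(counter)
            region.n_reads = sum(counter.values())
        regions.extend(contig_regions)
    return regions


def annotate_region(
    region: Region,
    k: int = DEFAULT_TOP_TAXA,
    organism: str = "",
    ref_id: str = "",
) -> BedRow:
    """Render a region as one extended-BED row with its top-k taxa.

    Taxa are ranked by descending read count, ties broken lexicographically
    by taxon label; only the k most abundant are recorded.
    """
    if k < 1:
        raise ValueError(f"top-taxon count k must be >= 1, got {k}")
    ranked = sorted(region.taxon_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return BedRow(
        organism=organism,
        ref_id=ref_id,
        contig_id=region.contig_id,
        start=region.start,
        end=region.end,
        length=region.length,
        n_reads=region.n_reads,
        taxon_fields=[(count, taxon) for taxon, count in ranked[:k]],
    )


def regions_to_bed(
    regions: Sequence[Region],
    k: int = DEFAULT_TOP_TAXA,
    organism: str = "",
    ref_id: str = "",
) -> list[BedRow]:
    return [annotate_region(r, k=k, organism=organism, ref_id=ref_id) for r in regions]


def _check_regions(
    regions: Sequence[Region], target: Sequence[SequenceRecord]
) -> dict[str, list[Region]]:
    lengths = {r.contig_id: r.length for r in target}
    per_contig: dict[str, list[Region]] = {c: [] for c in lengths}
    for region in regions:
        if region.contig_id not in lengths:
            raise ValueError(f"region on unknown contig {region.contig_id!r}")
        if region.end > lengths[region.contig_id]:
            raise ValueError(
                f"region [{region.start}, {region.end}) exceeds contig "
                f"{region.contig_id!r} length {lengths[region.contig_id]}"
            )
        per_contig[region.contig_id].append(region)
    for contig_id, chunk in per_contig.items():
        chunk.sort(key=lambda r: r.start)
        for a, b in zip(chunk, chunk[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping regions on {contig_id}: "
                    f"[{a.start},{a.end}) and [{b.start},{b.end})"
                )
    return per_contig


def breadth_of_coverage(
    regions: Sequence[Region], target: Sequence[SequenceRecord]
) -> tuple[float, dict[str, float]]:
    """Fraction of reference bases covered at least once, for the assembly
    as a whole and per contig."""
    per_contig_regions = _check_regions(regions, target)
    lengths = {r.contig_id: r.length for r in target}
    per_contig = {
        cid: sum(r.length for r in chunk) / lengths[cid] if lengths[cid] else 0.0
        for cid, chunk in per_contig_regions.items()
    }
    total = sum(lengths.values())
    covered = sum(r.length for r in regions)
    return (covered / total if total else 0.0), per_contig


@dataclass
class ContigFractionSummary:
    """Per-contig microbial-like fractions with a histogram and counts of the
    two extreme modes (fractions <= eps and >= 1 - eps)."""

    fractions: dict[str, float]
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    n_zero_mode: int
    n_one_mode: int
    eps: float = 0.01


def contig_fraction_distribution(
    regions: Sequence[Region],
    target: Sequence[SequenceRecord],
    bins: int = 100,
    eps: float = 0.01,
    restrict_to: Iterable[str] | None = None,
) -> ContigFractionSummary:
    """Distribution of microbial-like fractions across contigs.

    ``restrict_to`` limits the summary to a contig subset — e.g. only contigs
    with at least one aligned sample read, the conditioning used when judging
    where an environmental sample's reads land.
    """
    _, per_contig = breadth_of_coverage(regions, target)
    if restrict_to is not None:
        keep = set(restrict_to)
        per_contig = {c: f for c, f in per_contig.items() if c in keep}
    if not per_contig:
        raise ValueError("no contigs to summarize")
    values = np.array(list(per_contig.values()))
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return ContigFractionSummary(
        fractions=per_contig,
        hist_counts=counts,
        hist_edges=edges,
        n_zero_mode=int((values <= eps).sum()),
        n_one_mode=int((values >= 1 - eps).sum()),
        eps=eps,
    )


def genome_taxon_table(
    counts_by_assembly: Mapping[str, Mapping[str, int]],
    normalize: bool = True,
) -> pd.DataFrame:
    """Assemblies x taxa abundance matrix of pseudo-read alignment counts.

    When normalized, each taxon column is min-max scaled to [0, 1] across
    assemblies (0 = lowest, 1 = highest); constant columns map to 0. This is
    the matrix behind the genome-wide annotation heatmap.
    """
    if not counts_by_assembly or not any(
        counts_by_assembly[a] for a in counts_by_assembly
    ):
        raise ValueError("need at least one assembly with nonzero counts")
    table = (
        pd.DataFrame.from_dict(counts_by_assembly, orient="index")
        .fillna(0)
        .astype(float)
        .sort_index(axis=1)
    )
    if not normalize:
        return table
    col_min = table.min(axis=0)
    span = table.max(axis=0) - col_min
    normalized = (table - col_min).div(span.replace(0, np.nan), axis=1)
    return normalized.fillna(0.0)
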