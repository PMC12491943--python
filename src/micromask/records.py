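"""Core record types shared across the pipeline.

All genomic coordinates in this package are 0-based half-open, matching the
BED convention: a region ``[start, end)`` has length ``end - start``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (contig/scaffold/chromosome).

    ``organism`` doubles as the taxon label when the record belongs to a
    contaminant-source genome set; pseudo-reads fragmented from it inherit
    that label.
    """

    contig_id: str
    sequence: str
    assembly_id: str = ""
    organism: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class PseudoRead:
    """A fixed-length sliding window cut from a source genome.

    The read id encodes provenance as ``taxon|contig|start`` so that taxon
    attribution survives a round trip through FASTA and SAM.
    """

    taxon_label: str
    source_contig: str
    source_start: int
    sequence: str

    @property
    def read_id(self) -> str:
        return f"{self.taxon_label}|{self.source_contig}|{self.source_start}"


_READ_ID_RE = re.compile(r"^(?P<taxon>[^|]+)\|(?P<contig>[^|]+)\|(?P<start>\d+)$")


def parse_read_id(read_id: str) -> tuple[str, str, int] | None:
    """Parse ``taxon|contig|start`` back into its parts, or None if the id
    does not follow the pseudo-read convention (e.g. a sample read)."""
    m = _READ_ID_RE.match(read_id)
    if m is None:
        return None
    return m.group("taxon"), m.group("contig"), int(m.group("start"))


@dataclass
class AlignmentRecord:
    """One placement of a read on a target contig.

    ``rank`` orders a read's retained placements (1 = primary). ``taxon_label``
    is parsed from the read id for pseudo-reads and empty for sample reads.
    """

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    rank: int = 1
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty alignment interval [{self.start}, {self.end})")
        if not self.taxon_label:
            parsed = parse_read_id(self.read_id)
            if parsed is not None:
                self.taxon_label = parsed[0]

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Region:
    """A microbial-like interval: a maximal run of bases covered by at least
    one aligned pseudo-read, with supporting-read count and per-taxon
    attribution."""

    contig_id: str
    start: int
    end: int
    n_reads: int = 0
    taxon_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid region [{self.start}, {self.end}) on {self.contig_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BedRow:
    """One row of the extended BED dialect reporting a microbial-like region.

    ``taxon_fields`` holds the ranked ``(count, taxon_label)`` attributions
    that become the MICR1..MICRk columns.
    """

    organism: str
    ref_id: str
    contig_id: str
    start: int
    end: int
    length: int
    n_reads: int
    taxon_fields: list[tuple[int, str]] = field(default_factory=list)

    def validate(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"BED row on {self.contig_id}: start {self.start} >= end {self.end}"
            )
        if self.length != self.end - self.start:
            raise ValueError(
                f"BED row on {self.contig_id}: length {self.length} != "
                f"end - start = {self.end - self.start}"
            )
        counts = [c for c, _ in self.taxon_fields]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError("taxon field counts must be non-increasing")
        if any(c > self.n_reads for c in counts):
            raise ValueError("taxon field count exceeds NREADS")
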