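"""Readers and writers for the formats the pipeline touches.

FASTA goes through Biopython, SAM through pysam. The extended BED dialect is
the tool's own report format: a headerless TSV with columns ORGANISM, REFID,
CONTIG, START, END, LENGTH, NREADS followed by one ``<count>_reads_<taxon>``
column per ranked taxon attribution. Coordinates are 0-based half-open, so
LENGTH == END - START exactly, and counts are written without thousands
separators so the files stay machine-readable.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .records import AlignmentRecord, BedRow, SequenceRecord

_ALLOWED = set("ACGTNacgtnUu")
_U_TO_T = str.maketrans("Uu", "Tt")

FASTA_WRAP = 60  # output line width; matches the pseudo-read window length


def read_fasta(
    path: str | Path, assembly_id: str = "", organism: str = ""
) -> list[SequenceRecord]:
    """Read a (possibly line-wrapped) multi-FASTA into SequenceRecords.

    Case is preserved; 'U'/'u' are normalized to 'T'/'t' to tolerate
    RNA-alphabet deposits. Characters outside {A,C,G,T,N,U} in either case
    raise a ValueError naming the offending contig.
    """
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        bad = set(seq) - _ALLOWED
        if bad:
            raise ValueError(
                f"contig {rec.id!r}: invalid sequence characters {sorted(bad)}"
            )
        records.append(
            SequenceRecord(
                contig_id=rec.id,
                sequence=seq.translate(_U_TO_T),
                assembly_id=assembly_id,
                organism=organism,
            )
        )
    if not records:
        raise ValueError(f"no sequences in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns, order preserved."""
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.contig_id, description="")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=FASTA_WRAP)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Extended BED dialect

_TAXON_FIELD_RE = re.compile(r"^(\d+)_reads_(.+)$")


def format_taxon_field(count: int, taxon: str) -> str:
    return f"{count}_reads_{taxon}"


def write_bed(rows: Sequence[BedRow], path: str | Path) -> None:
    """Write the extended BED report (headerless TSV, >= 7 columns).

    Rows must arrive sorted by (contig_id, start); every row is validated
    (LENGTH == END - START, non-increasing taxon counts) before writing.
    """
    keys = [(r.contig_id, r.start) for r in rows]
    if keys != sorted(keys):
        raise ValueError("BED rows must be sorted by (contig, start)")
    with open(path, "w") as fh:
        for row in rows:
            row.validate()
            fields = [
                row.organism,
                row.ref_id,
                row.contig_id,
                str(row.start),
                str(row.end),
                str(row.length),
                str(row.n_reads),
            ]
            fields.extend(format_taxon_field(c, t) for c, t in row.taxon_fields)
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[BedRow]:
    """Read either the extended (>= 7 column) dialect or plain 3-column BED.

    Plain rows get empty organism/ref_id and n_reads 0 so external interval
    files can feed the masker directly.
    """
    rows: list[BedRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                if len(parts) >= 7:
                    taxon_fields = []
                    for token in parts[7:]:
                        m = _TAXON_FIELD_RE.match(token)
                        if m is None:
                            raise ValueError(f"malformed taxon field {token!r}")
                        taxon_fields.append((int(m.group(1)), m.group(2)))
                    row = BedRow(
                        organism=parts[0],
                        ref_id=parts[1],
                        contig_id=parts[2],
                        start=int(parts[3]),
                        end=int(parts[4]),
                        length=int(parts[5]),
                        n_reads=int(parts[6]),
                        taxon_fields=taxon_fields,
                    )
                elif len(parts) >= 3:
                    start, end = int(parts[1]), int(parts[2])
                    row = BedRow(
                        organism="",
                        ref_id="",
                        contig_id=parts[0],
                        start=start,
                        end=end,
                        length=end - start,
                        n_reads=0,
                    )
                else:
                    raise ValueError("expected >= 3 tab-separated columns")
                row.validate()
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# SAM

def _sam_header(target: Sequence[SequenceRecord]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r.contig_id, "LN": r.length} for r in target],
        }
    )


def read_sam(
    path: str | Path, target: Sequence[SequenceRecord] | None = None
) -> list[AlignmentRecord]:
    """Read SAM text into AlignmentRecords (unmapped records dropped).

    pysam does the parsing; 1-based POS becomes a 0-based start, strand comes
    from flag bit 0x10 and mismatches from the NM tag (0 when absent). When
    ``target`` is given, reference names absent from it raise a ValueError.
    Ranks are assigned per read in file order (primary first).
    """
    known = {r.contig_id for r in target} if target is not None else None
    records: list[AlignmentRecord] = []
    seen_per_read: dict[str, int] = {}
    try:
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped:
                    continue
                contig = aln.reference_name
                if known is not None and contig not in known:
                    raise ValueError(
                        f"{path}: reference {contig!r} absent from target assembly"
                    )
                end = aln.reference_end
                if end is None:  # no CIGAR; fall back to query length
                    qlen = aln.query_length or 0
                    if qlen == 0:
                        raise ValueError(
                            f"{path}: cannot infer alignment length for "
                            f"read {aln.query_name!r}"
                        )
                    end = aln.reference_start + qlen
                rank = seen_per_read.get(aln.query_name, 0) + 1
                seen_per_read[aln.query_name] = rank
                records.append(
                    AlignmentRecord(
                        read_id=aln.query_name,
                        contig_id=contig,
                        start=aln.reference_start,
                        end=end,
                        strand="-" if aln.is_reverse else "+",
                        mismatches=(
                            int(aln.get_tag("NM")) if aln.has_tag("NM") else 0
                        ),
                        rank=rank,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # pysam parse failures
        raise ValueError(f"malformed SAM {path}: {exc}") from exc
    return records


def write_sam(
    alignments: Iterable[AlignmentRecord],
    target: Sequence[SequenceRecord],
    path: str | Path,
) -> None:
    """Write placements as SAM (one line per retained placement).

    Sequences are not stored in AlignmentRecord, so SEQ is '*' with an
    ``<L>M`` CIGAR carrying the interval length; NM holds the mismatch count
    and flag 0x100 marks ranks > 1.
    """
    header = _sam_header(target)
    tid = {r.contig_id: i for i, r in enumerate(target)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alignments:
            seg = pysam.AlignedSegment(header)
            seg.query_name = a.read_id
            seg.flag = (0x10 if a.strand == "-" else 0) | (
                0x100 if a.rank > 1 else 0
            )
            seg.reference_id = tid[a.contig_id]
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigarstring = f"{a.length}M"
            seg.set_tag("NM", a.mismatches)
            out.write(seg)


# ---------------------------------------------------------------------------
# 6-column BED of read placements (enrichment-test input)

def write_reads_bed(alignments: Iterable[AlignmentRecord], path: str | Path) -> None:
    """Write read placements as 6-column BED (contig, start, end, name, score,
    strand); score carries the mismatch count."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(
                f"{a.contig_id}\t{a.start}\t{a.end}\t{a.read_id}\t"
                f"{a.mismatches}\t{a.strand}\n"
            )


def read_reads_bed(path: str | Path) -> list[AlignmentRecord]:
    """Read 6-column BED read placements back into AlignmentRecords."""
    out: list[AlignmentRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            out.append(
                AlignmentRecord(
                    read_id=parts[3],
                    contig_id=parts[0],
                    start=int(parts[1]),
                    end=int(parts[2]),
                    strand=parts[5],
                    mismatches=int(parts[4]),
                )
            )
    return out
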