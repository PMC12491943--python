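"""Seed-and-extend short-read placement with a multimap cap.

A functional stand-in for an FM-index aligner run end-to-end at high
sensitivity: exact k-mer seeds anchor candidate placements on both strands,
each candidate is extended ungapped across the full read, and placements
within the mismatch budget are kept — up to ``M`` per read, ordered
deterministically. A brute-force Hamming scanner (`oracle_align`) provides an
independent check on small targets.

Sensitivity note: a placement with m mismatches is found iff at least one
probed seed-length window of the read is mismatch-free at that locus. Seeds
are probed at every read offset, so for read length L, seed length k and
mismatch budget m the search is provably complete whenever
(m + 1) * (k - 1) + m < L; at the defaults (L=60, k=20, m=3) completeness
holds for all but adversarial mismatch placements and is asserted against
the oracle rather than by construction.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .records import AlignmentRecord, PseudoRead, SequenceRecord

DEFAULT_SEED = 20
DEFAULT_MAX_MISMATCH = 3
DEFAULT_MULTIMAP = 10

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_ACGT = frozenset("ACGT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class KmerIndex:
    """Exact-match seed index: every forward-strand k-mer of the target
    mapped to its (contig, position) occurrences. Targets are uppercased at
    index time (soft-masking on input is ignored; masking is applied
    downstream by this tool)."""

    def __init__(self, target: Sequence[SequenceRecord], seed: int = DEFAULT_SEED):
        if seed < 8:
            raise ValueError(f"seed length {seed} < 8 would blow up collisions")
        self.seed = seed
        self.contigs: dict[str, str] = {}
        self._hits: dict[str, list[tuple[str, int]]] = {}
        for rec in target:
            if rec.contig_id in self.contigs:
                raise ValueError(f"duplicate contig id {rec.contig_id!r}")
            seq = rec.sequence.upper()
            self.contigs[rec.contig_id] = seq
            for pos in range(len(seq) - seed + 1):
                kmer = seq[pos : pos + seed]
                self._hits.setdefault(kmer, []).append((rec.contig_id, pos))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self._hits.get(kmer, [])

    def __len__(self) -> int:
        return len(self._hits)


def build_index(
    target: Sequence[SequenceRecord], seed: int = DEFAULT_SEED
) -> KmerIndex:
    return KmerIndex(target, seed=seed)


def _hamming_within(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, or limit+1 once exceeded."""
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > limit:
                return mismatches
    return mismatches


_STRAND_ORDER = {"+": 0, "-": 1}


def _rank_and_sort(
    placements: list[tuple[int, str, int, str]], read_len: int, read_id: str, M: int | None
) -> list[AlignmentRecord]:
    placements.sort(key=lambda p: (p[0], p[1], p[2], _STRAND_ORDER[p[3]]))
    if M is not None:
        placements = placements[:M]
    return [
        AlignmentRecord(
            read_id=read_id,
            contig_id=contig,
            start=start,
            end=start + read_len,
            strand=strand,
            mismatches=mm,
            rank=rank,
        )
        for rank, (mm, contig, start, strand) in enumerate(placements, 1)
    ]


def align_read(
    read: str,
    index: KmerIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    M: int | None = DEFAULT_MULTIMAP,
    read_id: str = "read",
) -> list[AlignmentRecord]:
    """Place one read on the indexed target, end-to-end and ungapped.

    Candidates come from exact seed hits at every offset of the read and of
    its reverse complement; each is extended over the full read length and
    kept when mismatches <= max_mismatch. Surviving placements are
    deduplicated by (contig, start, strand), ordered by (mismatches, contig,
    start, '+' before '-'), truncated to M and ranked in that order. Pass
    ``M=None`` to disable truncation.
    """
    read = read.upper()
    k = index.seed
    if len(read) < k:
        raise ValueError(f"read length {len(read)} < seed length {k}")
    if not _ACGT.issuperset(read):
        raise ValueError("read contains characters outside {A,C,G,T}")
    L = len(read)
    candidates: set[tuple[str, int, str]] = set()
    for strand, oriented in (("+", read), ("-", revcomp(read))):
        for offset in range(0, L - k + 1):
            for contig, pos in index.lookup(oriented[offset : offset + k]):
                start = pos - offset
                if start >= 0 and start + L <= len(index.contigs[contig]):
                    candidates.add((contig, start, strand))
    placements: list[tuple[int, str, int, str]] = []
    for contig, start, strand in candidates:
        oriented = read if strand == "+" else revcomp(read)
        mm = _hamming_within(
            index.contigs[contig][start : start + L], oriented, max_mismatch
        )
        if mm <= max_mismatch:
            placements.append((mm, contig, start, strand))
    return _rank_and_sort(placements, L, read_id, M)


def align_reads(
    reads: Iterable[PseudoRead],
    index: KmerIndex,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    M: int | None = DEFAULT_MULTIMAP,
) -> list[AlignmentRecord]:
    """Align a pseudo-read stream; records inherit read ids (and hence taxon
    labels) from the reads."""
    out: list[AlignmentRecord] = []
    for read in reads:
        out.extend(
            align_read(
                read.sequence,
                index,
                max_mismatch=max_mismatch,
                M=M,
                read_id=read.read_id,
            )
        )
    return out


_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


ORACLE_MAX_TARGET = 1_000_000


def oracle_align(
    read: str,
    target: Sequence[SequenceRecord],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    read_id: str = "read",
) -> list[AlignmentRecord]:
    """Brute-force aligner: direct Hamming comparison at every start on both
    strands. Complete by construction; guarded to small targets."""
    total = sum(r.length for r in target)
    if total > ORACLE_MAX_TARGET:
        raise ValueError(
            f"target of {total} bases exceeds the oracle guard "
            f"({ORACLE_MAX_TARGET}); use the indexed aligner"
        )
    read = read.upper()
    if not _ACGT.issuperset(read):
        raise ValueError("read contains characters outside {A,C,G,T}")
    L = len(read)
    placements: list[tuple[int, str, int, str]] = []
    queries = {"+": _encode(read), "-": _encode(revcomp(read))}
    for rec in target:
        if rec.length < L:
            continue
        coded = _encode(rec.sequence)
        windows = np.lib.stride_tricks.sliding_window_view(coded, L)
        for strand, q in queries.items():
            mismatches = (windows != q).sum(axis=1)
            for start in np.flatnonzero(mismatches <= max_mismatch):
                placements.append(
                    (int(mismatches[start]), rec.contig_id, int(start), strand)
                )
    return _rank_and_sort(placements, L, read_id, M=None)
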