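"""Named synthetic fixtures exercising each pipeline capability.

Each preset builds a small study-in-a-box: a host assembly, contaminant
sources and whatever ground truth the scenario needs. The same presets back
the test suite, the examples and the `simulate` subcommand, so every claim
the package makes about itself is reproducible from a seed.
"""

from __future__ import annotations

from pathlib import Path

from .records import Region
from .seqio import write_bed, write_fasta, write_reads_bed
from .regions import regions_to_bed
from .synth import (
    SyntheticTruth,
    generate_host,
    generate_sources,
    plant_inserts,
    sample_reads,
)


def recovery_truth(seed: int = 214) -> SyntheticTruth:
    """Divergence-0 planted inserts for recall/precision measurement.

    One 60 kb host contig, three 8 kb source taxa, six 2.5 kb inserts.
    Inserts are kb-scale because the sliding window loses up to step-1 bases
    at each insert edge, which bounds attainable base recall for short
    inserts."""
    host = generate_host(2, [60_000, 30_000], seed=seed)
    sources = generate_sources(3, 8_000, seed=seed + 1)
    return plant_inserts(host, sources, n_inserts=6, insert_length=2_500,
                         divergence=0.0, copy_number=1, seed=seed + 2)


def multicopy_truth(seed: int = 214, divergence: float = 0.04) -> SyntheticTruth:
    """A single source fragment planted 12 times, each copy independently
    substituted at 4%.

    Pseudo-reads cut from the unmutated source then see each copy at ~4%
    divergence, so the expected number of copies within the 3-mismatch budget
    is 12 * P(Bin(60, 0.04) <= 3) ~= 9.4 — the regime where detected breadth
    keeps growing with the multimap cap and saturates near a cap of 10."""
    host = generate_host(1, 60_000, seed=seed)
    sources = generate_sources(1, 4_000, seed=seed + 1)
    return plant_inserts(host, sources, n_inserts=1, insert_length=2_000,
                         divergence=divergence, copy_number=12, seed=seed + 2)


def enrichment_fixture(
    seed: int = 214,
    n_reads: int = 2_000,
    inside_fraction: float = 1.0,
):
    """Host + fixed region set + sampled reads for the intersection test.

    Returns (host, regions, placements, read_records). Regions cover about
    30% of the assembly so the null expectation sits well away from both 0
    and 1."""
    host = generate_host(4, 20_000, seed=seed)
    regions: list[Region] = []
    import numpy as np

    rng = np.random.default_rng(seed + 1)
    for rec in host:
        pos = 0
        while pos < rec.length - 800:
            gap = int(rng.integers(400, 1_200))
            length = int(rng.integers(200, 600))
            start = pos + gap
            if start + length > rec.length:
                break
            regions.append(Region(rec.contig_id, start, start + length))
            pos = start + length
    placements, reads = sample_reads(
        host, regions, n_reads=n_reads, inside_fraction=inside_fraction,
        seed=seed + 2,
    )
    return host, regions, placements, reads


def bimodal_truth(seed: int = 214) -> SyntheticTruth:
    """50 pure-host contigs plus 50 contigs that are entirely source copies,
    giving the two-mode per-contig microbial-like fraction profile."""
    host = generate_host(100, 2_000, seed=seed)
    sources = generate_sources(5, 6_000, seed=seed + 1)
    # overwrite contigs 51..100 wholesale with (mutated) source fragments
    truth = plant_inserts(
        [rec for rec in host[50:]],
        sources,
        n_inserts=50,
        insert_length=2_000,
        divergence=0.0,
        copy_number=1,
        seed=seed + 2,
    )
    return SyntheticTruth(
        host=host[:50] + truth.host,
        sources=truth.sources,
        inserts=truth.inserts,
        seed=seed,
    )


def write_preset(name: str, out_dir: Path, seed: int = 214) -> list[Path]:
    """Materialize a preset as FASTA/BED files; returns the written paths."""
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_truth(truth: SyntheticTruth) -> None:
        host_path = out_dir / "host.fasta"
        truth_path = out_dir / "truth.bed"
        write_fasta(truth.host, host_path)
        # one FASTA per taxon: the CLI labels pseudo-reads by file stem
        by_taxon: dict[str, list] = {}
        for rec in truth.sources:
            by_taxon.setdefault(rec.organism, []).append(rec)
        for taxon, recs in by_taxon.items():
            path = out_dir / f"{taxon}.fasta"
            write_fasta(recs, path)
            written.append(path)
        rows = regions_to_bed(truth.truth_regions, k=1)
        # truth regions carry zero-count taxon attribution; keep plain rows
        for row in rows:
            row.taxon_fields = []
        write_bed(rows, truth_path)
        written.extend([host_path, truth_path])

    if name == "recovery":
        emit_truth(recovery_truth(seed))
    elif name == "multicopy":
        emit_truth(multicopy_truth(seed))
    elif name == "bimodal":
        emit_truth(bimodal_truth(seed))
    elif name == "enrichment":
        host, regions, placements, reads = enrichment_fixture(seed)
        write_fasta(host, out_dir / "host.fasta")
        rows = regions_to_bed(regions, k=1)
        for row in rows:
            row.taxon_fields = []
        write_bed(rows, out_dir / "regions.bed")
        write_reads_bed(placements, out_dir / "reads.bed")
        write_fasta(reads, out_dir / "reads.fasta")
        written.extend(
            out_dir / n for n in
            ["host.fasta", "regions.bed", "reads.bed", "reads.fasta"]
        )
    else:
        raise ValueError(f"unknown preset {name!r}")
    return written
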