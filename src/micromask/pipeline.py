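"""End-to-end workflows: detect (fragment → align → call → annotate → mask)
and validate (intersection enrichment + contig-fraction profile).

Both write their outputs plus a machine-readable run manifest (config,
package version, seeds, input checksums) so a run can be reproduced
byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__
from .aligner import align_reads, build_index
from .enrichment import EnrichmentResult, format_report, run_enrichment
from .masker import mask_fasta
from .pseudoreads import fragment_set
from .records import AlignmentRecord, Region, SequenceRecord
from .regions import (
    ContigFractionSummary,
    breadth_of_coverage,
    call_regions,
    contig_fraction_distribution,
    regions_to_bed,
)
from .seqio import read_sam, write_bed, write_fasta

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters. Window/step/multimap/top-taxa/permutation counts
    follow the published workflow; seed length and mismatch budget are this
    implementation's own aligner knobs."""

    window: int = 60
    step: int = 10
    multimap: int = 10
    max_mismatch: int = 3
    seed_length: int = 20
    top_taxa: int = 5
    n_perm: int = 300
    mask_mode: str = "hard"
    rng_seed: int = 214

    def validate(self) -> None:
        if not 1 <= self.step <= self.window:
            raise ValueError("need 1 <= step <= window")
        if self.multimap < 1 or self.top_taxa < 1 or self.n_perm < 1:
            raise ValueError("multimap, top_taxa and n_perm must be >= 1")
        if self.mask_mode not in ("hard", "soft"):
            raise ValueError("mask_mode must be 'hard' or 'soft'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Flat key = value text file mirroring the CLI flags."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.split("#")[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                kwargs[key] = value if key == "mask_mode" else int(value)
        config = cls(**kwargs)
        config.validate()
        return config


def _checksum(records: Sequence[SequenceRecord]) -> str:
    digest = hashlib.sha256()
    for rec in records:
        digest.update(rec.contig_id.encode())
        digest.update(rec.sequence.encode())
    return digest.hexdigest()


@dataclass
class DetectResult:
    regions: list[Region]
    assembly_breadth: float
    per_contig_breadth: dict[str, float]
    masked: list[SequenceRecord]
    per_taxon_reads: dict[str, int]
    manifest: dict


def detect(
    target: Sequence[SequenceRecord],
    sources: Sequence[SequenceRecord] | None,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
    sam_path: str | Path | None = None,
    organism: str = "",
    ref_id: str = "",
) -> DetectResult:
    """Run the full detection workflow on in-memory records.

    Sources are fragmented into pseudo-reads and aligned with the internal
    aligner, unless ``sam_path`` provides externally produced alignments
    (e.g. from a gapped aligner); regions are then called, annotated,
    summarized and masked. When ``out_dir`` is set the extended BED, breadth
    report, per-taxon counts, masked FASTA and run manifest are written there.
    """
    config = config or RunConfig()
    config.validate()
    stage = "setup"
    try:
        if sam_path is not None:
            stage = "sam ingestion"
            alignments = read_sam(sam_path, target=target)
            per_taxon: dict[str, int] = {}
        else:
            if sources is None:
                raise ValueError("need source genomes or a SAM file")
            stage = "fragmentation"
            reads, per_taxon = fragment_set(sources, w=config.window, s=config.step)
            stage = "alignment"
            index = build_index(target, seed=config.seed_length)
            alignments = align_reads(
                reads, index, max_mismatch=config.max_mismatch, M=config.multimap
            )
        stage = "region calling"
        regions = call_regions(alignments, target)
        stage = "breadth"
        assembly_breadth, per_contig = breadth_of_coverage(regions, target)
        stage = "masking"
        masked = mask_fasta(target, regions, config.mask_mode)
    except Exception as exc:
        raise RuntimeError(f"detect failed at stage {stage!r}: {exc}") from exc

    logger.info(
        "detect: %d alignments -> %d regions, breadth %.4f",
        len(alignments), len(regions), assembly_breadth,
    )
    manifest = {
        "tool": "micromask",
        "version": __version__,
        "command": "detect",
        "config": dataclasses.asdict(config),
        "target_checksum": _checksum(target),
        "source_checksum": _checksum(sources) if sources else None,
        "sam_input": str(sam_path) if sam_path else None,
        "n_alignments": len(alignments),
        "n_regions": len(regions),
        "assembly_breadth": assembly_breadth,
    }
    result = DetectResult(
        regions=regions,
        assembly_breadth=assembly_breadth,
        per_contig_breadth=per_contig,
        masked=masked,
        per_taxon_reads=per_taxon,
        manifest=manifest,
    )
    if out_dir is not None:
        _write_detect_outputs(result, config, Path(out_dir), organism, ref_id)
    return result


def _write_detect_outputs(
    result: DetectResult,
    config: RunConfig,
    out_dir: Path,
    organism: str,
    ref_id: str,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = regions_to_bed(
        result.regions, k=config.top_taxa, organism=organism, ref_id=ref_id
    )
    write_bed(rows, out_dir / "regions.bed")
    write_fasta(result.masked, out_dir / "masked.fasta")
    with open(out_dir / "breadth.tsv", "w") as fh:
        fh.write(f"assembly\t{result.assembly_breadth:.6f}\n")
        for contig_id, frac in sorted(result.per_contig_breadth.items()):
            fh.write(f"{contig_id}\t{frac:.6f}\n")
    with open(out_dir / "pseudoread_counts.tsv", "w") as fh:
        for taxon, count in sorted(result.per_taxon_reads.items()):
            fh.write(f"{taxon}\t{count}\n")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def validate(
    placements: Sequence[AlignmentRecord],
    regions: Sequence[Region],
    target: Sequence[SequenceRecord],
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[EnrichmentResult, ContigFractionSummary]:
    """Post-mapping validation: does the sample's signal come from the
    microbial-like regions?

    Runs the intersection-enrichment permutation test plus the contig
    microbial-like-fraction profile restricted to contigs with >= 1 mapped
    read.
    """
    config = config or RunConfig()
    config.validate()
    result = run_enrichment(
        placements, regions, target, n_perm=config.n_perm, seed=config.rng_seed
    )
    touched = {a.contig_id for a in placements}
    summary = contig_fraction_distribution(regions, target, restrict_to=touched)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "enrichment.tsv", "w") as fh:
            fh.write(format_report(result))
        with open(out_dir / "contig_fractions.tsv", "w") as fh:
            for contig_id, frac in sorted(summary.fractions.items()):
                fh.write(f"{contig_id}\t{frac:.6f}\n")
    return result, summary
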