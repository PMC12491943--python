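"""k-mer composition ordination of endogenous vs exogenous segments.

Detects microbial-like regions in a synthetic host, extracts the exogenous
(region) and endogenous (complement) sequence sets per contig, MinHash-
sketches each set, and embeds the pairwise Mash-distance matrix in 2-D with
classical metric scaling. Exogenous segments derive from the microbial
sources and endogenous ones from the host background, so the two groups
should form distinct clusters — quantified here by the silhouette of the
2-group labelling (1 = perfectly separated, 0 = overlapping).
"""

from micromask import (
    align_reads,
    build_index,
    call_regions,
    complement,
    distance_matrix,
    embed,
    extract_fasta,
    fragment_set,
    sketch,
)
from micromask.presets import recovery_truth

truth = recovery_truth(seed=214)
reads, _ = fragment_set(truth.sources)
regions = call_regions(align_reads(reads, build_index(truth.host)), truth.host)

sketches, labels = [], []
for contig in truth.host:
    per_contig = [r for r in regions if r.contig_id == contig.contig_id]
    exo = extract_fasta([contig], per_contig, min_length=500)
    endo = extract_fasta([contig], complement(per_contig, [contig]),
                         min_length=500)
    if exo:
        sketches.append(sketch(exo, f"{contig.contig_id}_exogenous"))
        labels.append("exogenous")
    if endo:
        sketches.append(sketch(endo, f"{contig.contig_id}_endogenous"))
        labels.append("endogenous")

matrix = distance_matrix(sketches)
coords = embed(matrix)
print(matrix.round(3))
print()
for (label, row), group in zip(coords.iterrows(), labels):
    print(f"{label:25s} ({group:10s}) axis1={row.axis1:+.4f} axis2={row.axis2:+.4f}")

try:
    from sklearn.metrics import silhouette_score

    score = silhouette_score(coords.values, labels)
    print(f"\nsilhouette of the exogenous/endogenous split: {score:.3f}")
except ImportError:
    pass
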