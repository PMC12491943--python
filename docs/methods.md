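# Methods

## Problem and model

A eukaryotic reference assembly is modelled as a mosaic: most bases are
endogenous host sequence, but some intervals are exogenous, having entered
the assembly from microbial DNA present in the sequenced sample. Detection
works by probing the assembly with a dense library of short fragments cut
from candidate contaminant genomes ("pseudo-reads") and declaring any base
covered by at least one aligned pseudo-read microbial-like. The unit of
report is the maximal covered run (region), with the count of supporting
pseudo-reads and the most abundant source taxa attached.

The approach deliberately over-calls: a region may reflect genuine
contamination, deep conservation, or convergence. For the intended use —
masking decoy sequence before profiling environmental/ancient DNA — a
conservative (over-masking) call is preferable to a false taxonomic
detection, since truly endogenous reads can still be attracted by the
unmasked remainder.

## Pipeline parameters

| parameter | default | meaning |
|---|---|---|
| window `w` | 60 bp | pseudo-read length; twice the ~30 bp specificity floor, typical aeDNA fragment size |
| step `s` | 10 bp | sliding-window stride; every source base is probed by up to 6 windows |
| multimap cap `M` | 10 | placements retained per read; detection of multicopy regions saturates near 10 |
| max_mismatch | 3 | ungapped end-to-end mismatch budget (5% of 60 bp) |
| seed length | 20 bp | exact-match anchor length of the internal aligner |
| top_taxa `k` | 5 | taxa recorded per region |
| n_perm | 300 | permutations of the enrichment null |
| mask mode | hard | `N` replacement; soft (lowercase) optional |
| sketch `k` / size | 21 / 1000 | MinHash k-mer size and bottom-sketch size |

Contigs shorter than `w` yield no pseudo-reads; no tail-anchored window is
emitted by default (strict sliding window), so up to `s − 1 = 9` bases at a
contig (or insert) end are unprobed. Windows containing non-ACGT characters
are dropped by default: the internal aligner is exact-alphabet and most
aligners refuse N-containing seeds anyway.

## Alignment

The internal aligner is a functional analog of an FM-index short-read
aligner run end-to-end at high sensitivity, not a reimplementation of one:
exact seed hits anchor candidates on both strands, extension is ungapped
over the full read, ties are broken deterministically by
(mismatches, contig, start, '+' before '−'), and ranks 1..M are assigned in
that order. Seeds are probed at **every** read offset rather than only at
non-overlapping tiles; this is a strict superset of tile probing at modest
cost and makes the search provably complete whenever
`(max_mismatch + 1)(seed − 1) + max_mismatch < read_length`. At the
defaults (60 bp, seed 20, 3 mismatches) that bound fails, so completeness
is asserted empirically against a brute-force Hamming oracle; the
oracle-equivalence suite runs at seed 14, where the bound holds
(4·13 + 3 = 55 < 60) and set equality is exact by construction. Gapped or
quality-aware alignment is delegated to external tools via SAM ingestion.

`NREADS` counts retained alignment records, so one pseudo-read mapping to a
region at several retained placements contributes each placement once —
matching per-base depth semantics, and the only reading consistent with
regions whose `NREADS` vastly exceeds any single taxon's count.

## Enrichment test

Primary placements only. A read intersects the region set iff its interval
overlaps any region by ≥ 1 base on the same contig. The null re-places each
read uniformly within its own contig, preserving read length and per-contig
read counts; contigs are not exchanged because the empirical question is
where reads sit *within* contigs. The p-value is the add-one estimator
`(1 + #{null ≥ observed})/(1 + n_perm)`, which never returns 0 and has
floor 1/301 = 0.003322 at 300 permutations; ties count against
significance. An exact enumeration oracle computes each read's overlap
probability over all valid starts, giving the analytic null expectation the
permutation mean must match (asserted at 3 Monte-Carlo SE). Reads longer
than their contig are excluded from both observed and null counts with a
warning. The null expectation always exceeds the masked-base fraction for
reads longer than 1 bp (overlap inflation): a window can overlap a region
without starting in it.

## Sketching and ordination

Canonical k-mers (lexicographic min of k-mer and reverse complement, which
coincides with numeric min under 2-bit A<C<G<T encoding) are hashed with a
seeded splitmix64 finalizer — deterministic across runs and platforms — and
the `sketch_size` smallest distinct hashes retained. Distance uses Mash's
joint-bottom estimator: j is the fraction of the bottom-s of the union
present in both sketches, with s = min(sketch_size, |union bottom|), so
identical inputs give j = 1 and d = 0 even when shorter than the sketch
size; disjoint sketches saturate at d = 1. "PCA on the distance matrix" is
interpreted as classical metric scaling (PCoA): double-center −½ D∘D, take
the leading eigenpairs, clamp negative eigenvalues to zero, and fix axis
signs by making each axis's largest-magnitude coordinate positive.

## Synthetic fixtures

The generator emulates exactly what the detection logic needs: i.i.d.
background hosts at a chosen GC, source genomes per taxon, inserts copied
at known coordinates with independent per-base substitution, and read
samples drawn from region-overlapping starts with probability
`inside_fraction`. It does **not** model repeats, indels, horizontal
transfer, sequencing error beyond uniform substitution, or realistic genome
evolution — so passing tests demonstrate the pipeline's interval logic,
attribution, calibration and masking semantics, not robustness to
repeat-rich real genomes. An optional aDNA-style terminal damage toggle
(5' C→T, 3' G→A) exists on read sampling, default off.

Fixture sizes were chosen so the full suite exercises kb–100 kb scales:

- *recovery*: 90 kb host, six 2.5 kb divergence-0 inserts from three 8 kb
  sources. Inserts are kb-scale because the strict sliding window loses up
  to `s − 1` bases at each insert edge; a 500 bp insert caps base recall at
  (500 − 18)/500 ≈ 0.964 regardless of implementation, while 2.5 kb permits
  the ≥ 0.99 recall the pipeline actually achieves.
- *multicopy*: one 2 kb fragment planted 12× at per-copy divergence 0.04.
  Reads cut from the unmutated source see each copy at ~4%, so the expected
  number of placements within the 3-mismatch budget is
  12·P(Bin(60, 0.04) ≤ 3) ≈ 9.4 — the regime where breadth grows with the
  multimap cap and saturates near M = 10 (defined a priori as ≤ 1% relative
  gain from M = 10 to M = 12). With identical copies the deterministic
  tie-break would instead grow breadth linearly up to M = copy number.
- *enrichment*: 4 × 20 kb host with ~30% of bases in regions, keeping the
  null expectation away from 0 and 1; calibration uses 200 repeats of
  200 reads at 59 permutations (with the add-one estimator,
  P(p ≤ 0.05) = 3/60 = 0.05 exactly under exchangeability), and the
  null-mean/oracle comparison uses 300 permutations.
- *self-alignment*: 20 genomes of 10–100 kb; per-genome breadth after
  realignment at mismatch 0 is analytically ≥ (L − 9)/L, so the median
  lands near 100%.

## Numerical and dialect choices

- All coordinates 0-based half-open; `LENGTH = END − START` exactly.
  BED counts are written without thousands separators.
- Region merging uses distance 0: adjacent covered bases join; intervals
  separated by ≥ 1 zero-depth base stay distinct.
- Taxon ranking ties break lexicographically; sample (unlabelled) reads
  never enter `NREADS` or taxon counts.
- Taxon-table normalization is per-taxon (column) min-max; constant columns
  map to 0. Per-genome or global normalization are defensible alternatives;
  per-taxon makes genomes comparable for each microbe.
- Masking merges overlapping input regions (tolerating third-party BEDs)
  and is idempotent; hard-masked bases can never be re-hit at mismatch 0.
- 'U'/'u' normalized to 'T'/'t' on FASTA input; output FASTA wraps at 60.
- RNG: numpy `default_rng` throughout, one seeded generator per call; the
  package-wide default seed is 214.

## Known limitations

- The internal aligner is ungapped; indel-containing contamination is only
  found via ingested external SAM.
- Seed-and-extend completeness at the default seed length is probabilistic
  for adversarial mismatch placements (see Alignment above).
- The brute-force oracle is guarded to ≤ 1 Mb total target.
- `read_sam` reports parse failures with file context but not always the
  exact offending line number (the underlying parser does not expose it).
- Enrichment uses a single region set; no multiple-testing control across
  assemblies, and no GC- or mappability-matched null.
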