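"""MinHash sketching, Mash distances and classical-MDS ordination.

Used to check that the extracted exogenous (microbial-like) and endogenous
segment sets separate by k-mer composition: each segment set is reduced to a
bottom sketch of the hash values of its canonical k-mers, pairwise Mash
distances d = -(1/k) ln(2j / (1 + j)) are assembled into a matrix, and the
matrix is embedded in 2-D by classical metric scaling (PCoA). Hashing is a
seeded splitmix64 finalizer over 2-bit-encoded k-mers, so sketches are
deterministic across runs and platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .records import SequenceRecord

DEFAULT_K = 21
DEFAULT_SKETCH_SIZE = 1000
HASH_SEED = np.uint64(0x9E2A83C1D5B79F03)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


def _splitmix64(x: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        x = (x ^ HASH_SEED) * np.uint64(0x9E3779B97F4A7C15)
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


def _canonical_kmer_ints(sequence: str, k: int) -> np.ndarray:
    """2-bit-packed canonical k-mers of one sequence; windows containing a
    non-ACGT base are skipped. Canonical = min(k-mer, reverse complement),
    which under A<C<G<T encoding equals the lexicographic rule."""
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.uint64)
    valid_base = codes != 255
    bad = np.concatenate([[0], np.cumsum(~valid_base)])
    window_valid = (bad[k:] - bad[:-k]) == 0
    safe = np.where(valid_base, codes, 0).astype(np.uint64)
    comp = np.uint64(3) - safe
    fwd = np.zeros(n - k + 1, dtype=np.uint64)
    rev = np.zeros(n - k + 1, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for j in range(k):
            fwd = (fwd << np.uint64(2)) | safe[j : n - k + 1 + j]
            rev |= comp[j : n - k + 1 + j] << np.uint64(2 * j)
    return np.minimum(fwd, rev)[window_valid]


@dataclass
class MinHashSketch:
    """Bottom sketch: the ``sketch_size`` smallest distinct 64-bit hashes of
    a sequence set's canonical k-mers, stored sorted ascending."""

    label: str
    k: int
    sketch_size: int
    hashes: np.ndarray

    def __post_init__(self) -> None:
        if len(self.hashes) > self.sketch_size:
            raise ValueError("sketch larger than sketch_size")
        if len(self.hashes) > 1 and not (np.diff(self.hashes) > 0).all():
            raise ValueError("sketch hashes must be strictly increasing")


def sketch(
    sequences: Sequence[SequenceRecord],
    label: str,
    k: int = DEFAULT_K,
    sketch_size: int = DEFAULT_SKETCH_SIZE,
) -> MinHashSketch:
    """Sketch a sequence set (k-mers never span record boundaries)."""
    pieces = [_canonical_kmer_ints(rec.sequence, k) for rec in sequences]
    kmers = np.unique(np.concatenate(pieces)) if pieces else np.empty(0, np.uint64)
    if kmers.size == 0:
        raise ValueError("no valid k-mers")
    hashes = np.sort(_splitmix64(kmers))
    return MinHashSketch(label=label, k=k, sketch_size=sketch_size,
                         hashes=hashes[:sketch_size])


def mash_distance(a: MinHashSketch, b: MinHashSketch) -> float:
    """Mash distance from the joint-bottom Jaccard estimate.

    j = |bottom-s of the union that lies in both sketches| / s with
    s = min(sketch_size, |bottom of union|); d = -(1/k) ln(2j/(1+j)),
    saturating at 1.0 when the sketches share nothing.
    """
    if a.k != b.k:
        raise ValueError(f"k-mer size mismatch: {a.k} != {b.k}")
    if a.sketch_size != b.sketch_size:
        raise ValueError("sketch_size mismatch")
    union = np.union1d(a.hashes, b.hashes)
    s = min(a.sketch_size, len(union))
    bottom = union[:s]
    shared = int((np.isin(bottom, a.hashes) & np.isin(bottom, b.hashes)).sum())
    j = shared / s
    if j == 0.0:
        return 1.0
    return max(0.0, -math.log(2 * j / (1 + j)) / a.k)


def distance_matrix(sketches: Sequence[MinHashSketch]) -> pd.DataFrame:
    """Symmetric zero-diagonal matrix of pairwise Mash distances."""
    if len(sketches) < 2:
        raise ValueError("need at least 2 sketches")
    labels = [s.label for s in sketches]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sketch labels")
    n = len(sketches)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = mash_distance(sketches[i], sketches[j])
    return pd.DataFrame(mat, index=labels, columns=labels)


def embed(matrix: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Classical metric scaling (PCoA) of a distance matrix.

    Double-centers -1/2 D∘D, takes the leading eigenvectors scaled by the
    square roots of their non-negative-clamped eigenvalues. Deterministic up
    to sign; each axis is flipped so its largest-magnitude coordinate is
    positive. An all-zero matrix maps every point to the origin.
    """
    D = np.asarray(matrix, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:n_components]
    coords = eigvecs[:, order] * np.sqrt(np.clip(eigvals[order], 0, None))
    for axis in range(coords.shape[1]):
        column = coords[:, axis]
        if column[np.argmax(np.abs(column))] < 0:
            coords[:, axis] = -column
    return pd.DataFrame(
        coords, index=matrix.index, columns=[f"axis{i+1}" for i in range(n_components)]
    )


# ---------------------------------------------------------------------------
# TSV persistence

def save_sketches(sketches: Sequence[MinHashSketch], path) -> None:
    """One sketch per line: label, k, sketch_size, comma-joined hex hashes."""
    with open(path, "w") as fh:
        for s in sketches:
            hashes = ",".join(format(int(h), "x") for h in s.hashes)
            fh.write(f"{s.label}\t{s.k}\t{s.sketch_size}\t{hashes}\n")


def load_sketches(path) -> list[MinHashSketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            label, k, size, hashes = line.rstrip("\n").split("\t")
            out.append(
                MinHashSketch(
                    label=label,
                    k=int(k),
                    sketch_size=int(size),
                    hashes=np.array(
                        [int(h, 16) for h in hashes.split(",")], dtype=np.uint64
                    ),
                )
            )
    return out
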