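"""MinHash sketches, Mash distances and the PCoA embedding."""

import math

import numpy as np
import pytest

from micromask import (
    MinHashSketch,
    SequenceRecord,
    distance_matrix,
    embed,
    generate_host,
    mash_distance,
    sketch,
)
from micromask.aligner import revcomp
from micromask.sketchdist import load_sketches, save_sketches
from micromask.synth import mutate


def _seq(length, seed):
    return generate_host(1, length, seed=seed)


class TestSketch:
    def test_deterministic_across_labels(self):
        records = _seq(5_000, 1)
        a = sketch(records, "a")
        b = sketch(records, "b")
        assert np.array_equal(a.hashes, b.hashes)

    def test_reverse_complement_invariance(self):
        records = _seq(5_000, 2)
        rc = [SequenceRecord("rc", revcomp(records[0].sequence))]
        assert np.array_equal(sketch(records, "f").hashes, sketch(rc, "r").hashes)

    def test_saturates_at_sketch_size(self):
        s = sketch(_seq(10_000, 3), "x", sketch_size=1000)
        assert len(s.hashes) == 1000
        assert (np.diff(s.hashes) > 0).all()

    def test_ambiguous_only_input_rejected(self):
        with pytest.raises(ValueError, match="no valid k-mers"):
            sketch([SequenceRecord("n", "N" * 100)], "n")

    def test_jaccard_estimate_tracks_true_jaccard(self):
        """Sketch Jaccard within 3 binomial SE of the exact k-mer Jaccard."""
        from micromask.sketchdist import _canonical_kmer_ints

        a = _seq(30_000, 4)
        rng = np.random.default_rng(5)
        mutated, _ = mutate(a[0].sequence, 0.01, rng)
        b = [SequenceRecord("m", mutated)]
        ka = set(_canonical_kmer_ints(a[0].sequence, 21).tolist())
        kb = set(_canonical_kmer_ints(mutated, 21).tolist())
        true_j = len(ka & kb) / len(ka | kb)
        size = 1000
        sa, sb = sketch(a, "a", sketch_size=size), sketch(b, "b", sketch_size=size)
        union = np.union1d(sa.hashes, sb.hashes)[:size]
        est = (np.isin(union, sa.hashes) & np.isin(union, sb.hashes)).mean()
        se = math.sqrt(true_j * (1 - true_j) / size)
        assert abs(est - true_j) <= 3 * se

    def test_tsv_round_trip(self, tmp_path):
        sketches = [sketch(_seq(3_000, s), f"g{s}") for s in range(3)]
        path = tmp_path / "sketches.tsv"
        save_sketches(sketches, path)
        back = load_sketches(path)
        for orig, loaded in zip(sketches, back):
            assert orig.label == loaded.label and orig.k == loaded.k
            assert np.array_equal(orig.hashes, loaded.hashes)


class TestMashDistance:
    def test_identical_sketches_distance_zero(self):
        s = sketch(_seq(5_000, 6), "x")
        assert mash_distance(s, s) == 0.0

    def test_formula_at_half_jaccard(self):
        # j = 0.5 -> d = -(1/21) ln(2*0.5/1.5)
        a = MinHashSketch("a", 21, 1000, np.arange(1000, dtype=np.uint64))
        b_hashes = np.concatenate(
            [np.arange(500, dtype=np.uint64), np.arange(2000, 2500, dtype=np.uint64)]
        )
        b = MinHashSketch("b", 21, 1000, b_hashes)
        # bottom-1000 of the union is 0..999, of which 0..499 are shared
        assert mash_distance(a, b) == pytest.approx(
            -math.log(2 * 0.5 / 1.5) / 21, abs=1e-12
        )

    def test_disjoint_sketches_saturate_at_one(self):
        a = MinHashSketch("a", 21, 4, np.array([1, 2, 3, 4], dtype=np.uint64))
        b = MinHashSketch("b", 21, 4, np.array([5, 6, 7, 8], dtype=np.uint64))
        assert mash_distance(a, b) == 1.0

    def test_k_mismatch_rejected(self):
        a = sketch(_seq(3_000, 7), "a", k=21)
        b = sketch(_seq(3_000, 8), "b", k=15)
        with pytest.raises(ValueError):
            mash_distance(a, b)

    def test_distance_monotone_in_mutation_rate(self):
        base = _seq(20_000, 9)
        ref = sketch(base, "ref")
        rng = np.random.default_rng(10)
        distances = []
        for rate in (0.0, 0.01, 0.05, 0.1):
            mutated, _ = mutate(base[0].sequence, rate, rng)
            distances.append(
                mash_distance(ref, sketch([SequenceRecord("m", mutated)], "m"))
            )
        assert distances == sorted(distances)
        assert distances[0] == 0.0


class TestMatrixAndEmbedding:
    def test_identical_inputs_zero_matrix(self):
        records = _seq(4_000, 11)
        sketches = [
            MinHashSketch(f"s{i}", 21, 1000, sketch(records, "x").hashes)
            for i in range(3)
        ]
        matrix = distance_matrix(sketches)
        assert (matrix.values == 0).all()

    def test_symmetry_and_zero_diagonal(self):
        sketches = [sketch(_seq(4_000, 20 + i), f"g{i}") for i in range(4)]
        matrix = distance_matrix(sketches)
        assert np.allclose(matrix.values, matrix.values.T)
        assert np.allclose(np.diag(matrix.values), 0)

    def test_duplicate_labels_rejected(self):
        s = sketch(_seq(3_000, 30), "dup")
        with pytest.raises(ValueError):
            distance_matrix([s, s])

    def test_two_point_embedding_recovers_distance(self):
        import pandas as pd

        matrix = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"],
                              columns=["a", "b"])
        coords = embed(matrix)
        gap = abs(coords.loc["a", "axis1"] - coords.loc["b", "axis1"])
        assert gap == pytest.approx(0.4, abs=1e-12)

    def test_three_point_distances_reproduced(self):
        import pandas as pd

        # any 3-point metric configuration embeds exactly in 2-D
        matrix = pd.DataFrame(
            [[0, 0.3, 0.5], [0.3, 0, 0.4], [0.5, 0.4, 0]],
            index=list("abc"), columns=list("abc"), dtype=float,
        )
        coords = embed(matrix).values
        for i in range(3):
            for j in range(3):
                dist = np.linalg.norm(coords[i] - coords[j])
                assert dist == pytest.approx(matrix.values[i, j], abs=1e-9)

    def test_label_order_invariance_up_to_sign(self):
        sketches = [sketch(_seq(4_000, 40 + i), f"g{i}") for i in range(4)]
        m1 = distance_matrix(sketches)
        m2 = distance_matrix(sketches[::-1]).loc[m1.index, m1.columns]
        c1, c2 = embed(m1).values, embed(m2).values
        for axis in range(2):
            assert np.allclose(c1[:, axis], c2[:, axis], atol=1e-9) or np.allclose(
                c1[:, axis], -c2[:, axis], atol=1e-9
            )

    def test_composition_groups_separate(self):
        """Two mutation families (Fig-4-style endogenous vs exogenous
        stand-ins) have larger between-group than within-group distances."""
        rng = np.random.default_rng(50)
        ancestors = [_seq(10_000, 60)[0], _seq(10_000, 61)[0]]
        sketches, groups = [], []
        for g, anc in enumerate(ancestors):
            for i in range(4):
                seq, _ = mutate(anc.sequence, 0.02, rng)
                sketches.append(
                    sketch([SequenceRecord("m", seq)], f"g{g}_{i}")
                )
                groups.append(g)
        matrix = distance_matrix(sketches).values
        groups = np.array(groups)
        within = matrix[np.ix_(groups == 0, groups == 0)]
        between = matrix[np.ix_(groups == 0, groups == 1)]
        assert within[np.triu_indices_from(within, 1)].mean() < between.mean()
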