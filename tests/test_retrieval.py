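"""Retrieval ranking and metrics: dense vs index-backed paths, tie
handling, and the metric identities they must satisfy."""

import itertools

import numpy as np
import pytest

from amore.encoders import (
    InvariantToyEncoder,
    NoisySyntheticEncoder,
    StackedLayersEncoder,
)
from amore.retrieval import (
    DistanceKind,
    RankVector,
    accuracy_at_k,
    evaluate_retrieval,
    layer_sweep,
    mean_reciprocal_rank,
    pairwise_distances,
    rank_true_pairs,
    recall_curve,
)

EXACT_KINDS = [DistanceKind.EUCLIDEAN_L2, DistanceKind.COSINE, DistanceKind.INNER_PRODUCT]


def scalar_distance(a, b, kind):
    if kind is DistanceKind.EUCLIDEAN_L2:
        return sum((x - y) ** 2 for x, y in zip(a, b)) ** 0.5
    dot = sum(x * y for x, y in zip(a, b))
    if kind is DistanceKind.INNER_PRODUCT:
        return -dot
    na = sum(x * x for x in a) ** 0.5
    nb = sum(y * y for y in b) ** 0.5
    return 1 - dot / (na * nb)


class TestPairwiseDistances:
    @pytest.mark.parametrize("kind", EXACT_KINDS)
    def test_matches_scalar_loop_oracle(self, kind):
        rng = np.random.default_rng(3)
        A, B = rng.standard_normal((5, 3)), rng.standard_normal((4, 3))
        D = pairwise_distances(A, B, kind)
        for i in range(5):
            for j in range(4):
                assert D[i, j] == pytest.approx(scalar_distance(A[i], B[j], kind), abs=1e-9)

    def test_self_distance_zero_euclidean(self):
        A = np.eye(4)
        assert np.allclose(np.diag(pairwise_distances(A, A, DistanceKind.EUCLIDEAN_L2)), 0)

    def test_cosine_geometry(self):
        A = np.array([[1.0, 0.0]])
        B = np.array([[1.0, 0.0], [0.0, 1.0]])
        D = pairwise_distances(A, B, DistanceKind.COSINE)
        assert D[0, 0] == pytest.approx(0.0)        # parallel
        assert D[0, 1] == pytest.approx(1.0)        # orthogonal: one unit farther

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            pairwise_distances(np.zeros((2, 3)), np.zeros((2, 4)), DistanceKind.EUCLIDEAN_L2)


class TestRankTruePairs:
    def test_hand_built_three_point_case(self):
        # aug of item 0 sits nearer to orig 1 than aug 1 does
        orig = np.array([[0.0, 0.0], [10.0, 0.0], [20.0, 0.0]])
        aug = np.array([[9.0, 0.0], [11.0, 0.0], [20.0, 1.0]])
        # distances from orig 0: to aug0 9, aug1 11, aug2 ~20 -> rank 1
        # from orig 1: aug0 at 1, aug1 at 1 -> tie, aug0 has smaller index
        rv = rank_true_pairs(orig, aug, DistanceKind.EUCLIDEAN_L2)
        assert rv.ranks.tolist() == [1, 2, 1]

    def test_invariant_encoder_ranks_all_first(self, handful_smiles):
        enc = InvariantToyEncoder()
        orig = enc.encode(handful_smiles).last_layer
        rv = rank_true_pairs(orig, orig.copy(), DistanceKind.EUCLIDEAN_L2)
        assert (rv.ranks == 1).all()

    def test_exact_tie_uses_index_tie_break(self):
        orig = np.array([[0.0], [5.0]])
        aug = np.array([[1.0], [1.0]])  # duplicated rows: exact tie everywhere
        rv = rank_true_pairs(orig, aug, DistanceKind.EUCLIDEAN_L2)
        # query 0: true index 0 wins the tie (smaller index) -> rank 1
        # query 1: true index 1 loses the tie to index 0 -> rank 2
        assert rv.ranks.tolist() == [1, 2]
        again = rank_true_pairs(orig, aug, DistanceKind.EUCLIDEAN_L2)
        assert np.array_equal(rv.ranks, again.ranks)

    @pytest.mark.parametrize("kind", EXACT_KINDS)
    def test_index_backend_matches_dense(self, kind):
        rng = np.random.default_rng(11)
        n, d = 60, 16
        orig = rng.standard_normal((n, d))
        aug = rng.standard_normal((n, d))
        dense = rank_true_pairs(orig, aug, kind, backend="dense")
        index = rank_true_pairs(orig, aug, kind, backend="index")
        assert np.array_equal(dense.ranks, index.ranks)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            rank_true_pairs(np.zeros((3, 2)), np.zeros((4, 2)))

    def test_approx_backend_returns_valid_ranks(self, standard_records):
        enc = InvariantToyEncoder(d=64)
        orig = enc.encode([r.smiles for r in standard_records]).last_layer
        rng = np.random.default_rng(0)
        aug = orig + 1e-6 * rng.standard_normal(orig.shape)
        rv = rank_true_pairs(orig, aug, backend="approx", seed=0)
        assert rv.n == len(standard_records)
        assert (rv.ranks >= 1).all()
        # near-duplicate embeddings: the graph index should find nearly all
        assert accuracy_at_k(rv, 1) >= 0.9


class TestMetrics:
    def test_accuracy_examples(self):
        rv = RankVector(np.array([1, 2, 4]))
        assert accuracy_at_k(rv, 1) == pytest.approx(1 / 3)
        assert accuracy_at_k(rv, 5) == 1.0

    def test_accuracy_matches_counting_oracle(self):
        rng = np.random.default_rng(5)
        ranks = rng.integers(1, 21, size=20)
        rv = RankVector(ranks)
        for k in (1, 3, 10):
            assert accuracy_at_k(rv, k) == sum(r <= k for r in ranks) / 20

    def test_mrr_examples(self):
        assert mean_reciprocal_rank(RankVector(np.array([1, 2, 4]))) == pytest.approx(
            (1 + 0.5 + 0.25) / 3
        )
        assert mean_reciprocal_rank(RankVector(np.array([1, 1, 1]))) == 1.0

    def test_mrr_uniform_enumeration_matches_harmonic_mean(self):
        # all 4^4 equally likely rank assignments for n=4
        n = 4
        total = 0.0
        count = 0
        for ranks in itertools.product(range(1, n + 1), repeat=n):
            total += mean_reciprocal_rank(RankVector(np.array(ranks)))
            count += 1
        H4 = sum(1 / r for r in range(1, n + 1))
        assert total / count == pytest.approx(H4 / n)
        assert H4 / n == pytest.approx(0.520833333, abs=1e-9)

    def test_recall_curve_example_and_monotonicity(self):
        rv = RankVector(np.array([1, 2, 4]))
        curve = recall_curve(rv, [1, 2, 3, 4])
        assert [curve[k] for k in (1, 2, 3, 4)] == pytest.approx([1 / 3, 2 / 3, 2 / 3, 1.0])
        vals = list(curve.values())
        assert all(a <= b for a, b in zip(vals, vals[1:]))
        assert curve[4] == 1.0  # Recall reaches 1 at K = pool size

    def test_recall_matches_accuracy_pointwise(self):
        rng = np.random.default_rng(8)
        rv = RankVector(rng.integers(1, 31, size=30))
        curve = recall_curve(rv, [1, 5, 10, 30])
        for k, v in curve.items():
            assert v == accuracy_at_k(rv, k)

    def test_rank_bounds_enforced(self):
        with pytest.raises(ValueError, match="1-based"):
            RankVector(np.array([0, 1]))
        with pytest.raises(ValueError, match="1..2"):
            RankVector(np.array([1, 3]), pool_size=2)


class TestNormalizedEquivalence:
    def test_unit_rows_give_identical_rankings(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            orig = rng.standard_normal((40, 8))
            aug = rng.standard_normal((40, 8))
            orig /= np.linalg.norm(orig, axis=1, keepdims=True)
            aug /= np.linalg.norm(aug, axis=1, keepdims=True)
            ranks = [rank_true_pairs(orig, aug, k).ranks for k in EXACT_KINDS]
            assert np.array_equal(ranks[0], ranks[1])
            assert np.array_equal(ranks[1], ranks[2])


class TestEvaluateRetrieval:
    def test_report_invariants_and_changed_block(self, handful_smiles):
        enc = NoisySyntheticEncoder(rho=0.6, seed=2, salt="o")
        orig = enc.encode(handful_smiles).last_layer
        aug = enc.with_salt("a").encode(handful_smiles).last_layer
        changed = np.arange(len(handful_smiles)) % 2 == 0
        rep = evaluate_retrieval(orig, aug, changed_mask=changed)
        assert rep.acc_at_1 <= rep.acc_at_5 <= 1.0
        assert rep.acc_at_1 <= rep.mrr <= 1.0
        assert rep.n_changed == int(changed.sum())
        assert set(rep.changed_only) == {"acc_at_1", "acc_at_5", "mrr"}
        assert rep.recall_curve[rep.n] == 1.0


class TestLayerSweep:
    def test_signal_layer_dominates_noise_layer(self, standard_records):
        smiles = [r.smiles for r in standard_records]
        noise = NoisySyntheticEncoder(rho=0.0, seed=0, d=64, salt="o")
        signal = NoisySyntheticEncoder(rho=1.0, seed=0, d=64, salt="o")
        orig = StackedLayersEncoder({0: noise, 1: signal}).encode(smiles)
        aug_noise = noise.with_salt("a")
        aug = StackedLayersEncoder({0: aug_noise, 1: signal}).encode(smiles)
        sweep = layer_sweep(orig, aug)
        assert sweep[1] == 1.0
        assert sweep[0] < 0.2  # near chance level 1/n

    def test_single_layer_sweep_equals_plain_accuracy(self, handful_smiles):
        enc = InvariantToyEncoder(d=32)
        orig = enc.encode(handful_smiles)
        sweep = layer_sweep(orig, orig)
        assert sweep == {0: 1.0}

    def test_layer_set_mismatch_rejected(self, handful_smiles):
        a = InvariantToyEncoder(d=8).encode(handful_smiles)
        b = StackedLayersEncoder(
            {0: InvariantToyEncoder(d=8), 1: InvariantToyEncoder(d=8)}
        ).encode(handful_smiles)
        with pytest.raises(ValueError, match="layer sets"):
            layer_sweep(a, b)
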