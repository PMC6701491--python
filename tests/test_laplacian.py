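import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncrank.config import RunConfig
from lncrank.laplacian import (
    CONSTANT_SENTINEL,
    FeatureScore,
    build_affinity_graph,
    laplacian_scores,
    merge_partition,
    partition_all_categories,
    partition_by_gaps,
    select_features,
    standardize,
)

from conftest import ALL_RANKS_12, make_table


def dense_laplacian_scores(X, k, bandwidth):
    """Independent dense evaluation of the locality-preservation score."""
    n = X.shape[0]
    D2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    t = bandwidth
    W = np.zeros((n, n))
    for i in range(n):
        order = [j for j in np.argsort(D2[i], kind="stable") if j != i][:k]
        for j in order:
            W[i, j] = np.exp(-D2[i, j] / t)
    W = np.maximum(W, W.T)
    np.fill_diagonal(W, 0.0)
    d = W.sum(1)
    L = np.diag(d) - W
    scores = []
    for r in range(X.shape[1]):
        f = X[:, r]
        ft = f - (f @ d) / d.sum()
        scores.append((ft @ L @ ft) / (ft @ np.diag(d) @ ft))
    return np.array(scores)


class TestAffinityGraph:
    def test_collinear_points_hand_built(self):
        # 4 points on a line spaced 1 apart, k=1: each links to a unit-gap
        # neighbour, union-symmetrized, weight e^{-1}
        table = make_table(np.array([[0.0], [1.0], [2.0], [3.0]]))
        g = build_affinity_graph(table, k=1, bandwidth=1.0, pre_standardized=True)
        W = g.W.toarray()
        assert np.allclose(W, W.T)
        assert np.allclose(np.diag(W), 0)
        nz = W[W > 0]
        assert np.allclose(nz, np.exp(-1.0))
        # middle points have two unit-gap neighbours via the union rule
        assert W[1, 0] > 0 and W[1, 2] > 0

    def test_identical_samples_weight_one(self):
        table = make_table(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        g = build_affinity_graph(table, k=1, bandwidth=1.0, pre_standardized=True)
        assert g.W[0, 1] == pytest.approx(1.0)  # e^0

    def test_laplacian_row_sums_zero_and_psd(self):
        rng = np.random.default_rng(4)
        table = make_table(rng.normal(size=(15, 3)))
        g = build_affinity_graph(table, k=3)
        L = np.diag(g.degrees) - g.W.toarray()
        assert np.allclose(L.sum(axis=1), 0, atol=1e-12)
        eigs = np.linalg.eigvalsh(L)
        assert eigs.min() > -1e-10

    def test_k_at_least_n_rejected(self):
        table = make_table(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="smaller than the sample count"):
            build_affinity_graph(table, k=3)


class TestLaplacianScores:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(10, 31), rng.integers(2, 11)
        X = standardize(rng.normal(size=(n, p)))
        table = make_table(X, names=[f"Gen_f{j}" for j in range(p)])
        g = build_affinity_graph(table, k=5 if n > 6 else 2,
                                 bandwidth=1.0, pre_standardized=True)
        mine = np.array(
            [s.score for s in laplacian_scores(table, g, pre_standardized=True)]
        )
        want = dense_laplacian_scores(X, k=g.k, bandwidth=1.0)
        np.testing.assert_allclose(mine, want, atol=1e-10)

    def test_constant_feature_gets_sentinel(self, caplog):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(12, 3))
        X[:, 1] = 7.0
        table = make_table(X)
        g = build_affinity_graph(table, k=2)
        with caplog.at_level("WARNING"):
            scores = laplacian_scores(table, g)
        assert scores[1].score == CONSTANT_SENTINEL
        assert "constant" in caplog.text

    def test_scores_within_normalized_laplacian_bound(self, small_benchmark):
        table, _, _ = small_benchmark
        g = build_affinity_graph(table, k=5)
        scores = laplacian_scores(table, g)
        vals = np.array([s.score for s in scores])
        assert (vals >= 0).all() and (vals <= 2 + 1e-9).all()

    def test_scale_invariance_of_one_feature(self):
        # the score is built on standardized columns, so a positive
        # rescaling of any single raw column cannot change anything
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 4))
        t1 = make_table(X)
        X2 = X.copy()
        X2[:, 2] *= 37.5
        t2 = make_table(X2)
        s1 = laplacian_scores(t1, build_affinity_graph(t1, k=4))
        s2 = laplacian_scores(t2, build_affinity_graph(t2, k=4))
        np.testing.assert_allclose(
            [s.score for s in s1], [s.score for s in s2], atol=1e-10
        )

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        t1 = make_table(X)
        perm = rng.permutation(30)
        t2 = make_table(X[perm], gene_ids=[f"g{i}" for i in perm])
        s1 = laplacian_scores(t1, build_affinity_graph(t1, k=4))
        s2 = laplacian_scores(t2, build_affinity_graph(t2, k=4))
        np.testing.assert_allclose(
            [s.score for s in s1], [s.score for s in s2], atol=1e-10
        )


def scores_from(vals, category="Genomic"):
    return [FeatureScore(f"f{i}", category, v) for i, v in enumerate(vals)]


class TestGapPartition:
    def test_worked_example(self):
        p = partition_by_gaps(scores_from([0.05, 0.10, 0.40, 0.45, 0.80]), (1, 2))
        assert p.lower == ["f0", "f1"]
        assert p.middle == ["f2", "f3"]
        assert p.upper == ["f4"]
        assert sorted(g for _, g in p.thresholds) == pytest.approx([0.30, 0.35])

    def test_tied_gaps_break_toward_earlier_position(self):
        # gaps: [0.1, 0.4, 0.4]; ranks (1,2) must take positions 1 then 2
        p = partition_by_gaps(scores_from([0.0, 0.1, 0.5, 0.9]), (1, 2))
        assert p.lower == ["f0", "f1"]
        assert p.middle == ["f2"]
        assert p.upper == ["f3"]

    def test_second_and_third_ranked_gaps(self):
        # gaps: [0.05, 0.30, 0.05, 0.35]; ranks (2,3) -> 0.30 then first 0.05
        p = partition_by_gaps(scores_from([0.05, 0.10, 0.40, 0.45, 0.80]), (2, 3))
        assert p.lower == ["f0"]
        assert p.middle == ["f1"]
        assert p.upper == ["f2", "f3", "f4"]

    def test_fewer_than_four_features_not_split(self, caplog):
        with caplog.at_level("WARNING"):
            p = partition_by_gaps(scores_from([0.1, 0.2, 0.3]), (1, 2))
        assert p.lower == ["f0", "f1", "f2"]
        assert p.middle == [] and p.upper == []

    def test_sentinel_scores_land_in_upper(self):
        scores = scores_from([0.1, 0.2, 0.6, 0.61, 1.0])
        scores.append(FeatureScore("fconst", "Genomic", CONSTANT_SENTINEL))
        p = partition_by_gaps(scores, (1, 2))
        assert "fconst" in p.upper

    @given(
        vals=st.lists(
            st.floats(min_value=0, max_value=2, allow_nan=False), min_size=4,
            max_size=20, unique=True,
        )
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_parts_partition_and_respect_score_order(self, vals):
        scores = scores_from(vals)
        p = partition_by_gaps(scores, (1, 2))
        by_name = {s.name: s.score for s in scores}
        assert sorted(p.lower + p.middle + p.upper) == sorted(by_name)
        if p.middle:
            assert max(by_name[n] for n in p.lower) < min(by_name[n] for n in p.middle)
        if p.middle and p.upper:
            assert max(by_name[n] for n in p.middle) < min(by_name[n] for n in p.upper)
        assert p.lower and p.middle and p.upper


class TestMergePartition:
    def test_mean_merge_arithmetic(self):
        table = make_table(
            np.array([[1.0, 3.0, 9.0], [2.0, 4.0, 9.0], [0.0, 0.0, 9.0]]),
            names=["Gen_a", "Gen_b", "Gen_c"],
        )
        parts = partition_all_categories(
            [FeatureScore("Gen_c", "Genomic", 0.1),
             FeatureScore("Gen_a", "Genomic", 0.5),
             FeatureScore("Gen_b", "Genomic", 0.55)],
        )
        # force the toy split: lower={c}, middle={a,b}, upper={}
        parts["Genomic"].lower = ["Gen_c"]
        parts["Genomic"].middle = ["Gen_a", "Gen_b"]
        parts["Genomic"].upper = []
        merged = merge_partition(table, parts)
        assert merged.feature_names == ["Gen_c", "Gen_LevelOne"]
        np.testing.assert_allclose(merged.values[:, 1], [2.0, 3.0, 0.0])
        assert merged.features[1].synthetic

    def test_empty_middle_emits_only_level_two(self):
        table = make_table(np.arange(8.0).reshape(4, 2), names=["Gen_a", "Gen_b"])
        parts = partition_all_categories(
            [FeatureScore("Gen_a", "Genomic", 0.1),
             FeatureScore("Gen_b", "Genomic", 0.9)]
        )
        parts["Genomic"].lower = ["Gen_a"]
        parts["Genomic"].middle = []
        parts["Genomic"].upper = ["Gen_b"]
        merged = merge_partition(table, parts)
        assert merged.feature_names == ["Gen_a", "Gen_LevelTwo"]

    def test_unknown_feature_is_hard_error(self):
        table = make_table(np.zeros((3, 1)), names=["Gen_a"])
        parts = partition_all_categories([FeatureScore("Gen_a", "Genomic", 0.1)])
        parts["Genomic"].lower = ["Gen_a", "Gen_ghost"]
        with pytest.raises(ValueError, match="unknown features"):
            merge_partition(table, parts)

    def test_column_count_is_lower_plus_merged_parts(self):
        rng = np.random.default_rng(0)
        table = make_table(rng.normal(size=(6, 5)),
                           names=[f"Net_f{i}" for i in range(5)],
                           categories=["Network"] * 5)
        # 5 features -> lower 2 + LevelOne + LevelTwo
        merged = merge_partition(
            table,
            {"Network": partition_by_gaps(
                [FeatureScore(f"Net_f{i}", "Network", v)
                 for i, v in enumerate([0.01, 0.02, 0.4, 0.45, 0.9])], (1, 2)
            )},
        )
        assert len(merged.features) == 4
        assert [f.name for f in merged.features if f.synthetic] == [
            "Net_LevelOne", "Net_LevelTwo"
        ]


class TestEndToEndSelection:
    def test_planted_tiers_recovered_and_eight_synthetic(self, small_benchmark):
        table, _, truth = small_benchmark
        reduced, scores, parts = select_features(
            table, RunConfig(gap_ranks=ALL_RANKS_12)
        )
        for cat, part in parts.items():
            assert set(part.lower) == set(truth.tiers[cat]["smooth"])
            assert set(part.middle) == set(truth.tiers[cat]["mid"])
        syn = [f.name for f in reduced.features if f.synthetic]
        assert len(syn) == 8  # two merged columns per category
        assert len(reduced.features) == sum(
            len(p.lower) for p in parts.values()
        ) + 8

    def test_default_config_keeps_three_parts_per_category(self, small_benchmark):
        # the Epigenetic override (2nd+3rd ranked gaps) still yields three
        # non-empty parts on the planted spectrum
        table, _, _ = small_benchmark
        _, _, parts = select_features(table, RunConfig())
        for part in parts.values():
            assert part.lower and part.middle and part.upper
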