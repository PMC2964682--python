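import numpy as np
import pytest

from oracles import brute_force_kernel_knn, pair_count_auc, two_sample_t_pvalue

from fluxdrn.errors import UndefinedStatisticError, ValidationError
from fluxdrn.predict import (
    CVConfig,
    InteractionMatrix,
    auc,
    baseline_scores,
    compare_auc,
    cross_validate,
    grid_search,
    kernel_knn_scores,
    loocv,
)
from fluxdrn.profiles import SimilarityMatrix


def sim_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"r{i}" for i in range(values.shape[0])]
    return SimilarityMatrix(ids, (values + values.T) / 2)


def random_instance(rng, n_reactions, n_drugs):
    ids = [f"r{i:02d}" for i in range(n_reactions)]
    raw = rng.uniform(-1, 1, size=(n_reactions, n_reactions))
    vals = (raw + raw.T) / 2
    np.fill_diagonal(vals, 1.0)
    sim = SimilarityMatrix(ids, vals)
    x = rng.integers(0, 2, size=(n_drugs, n_reactions)).astype(np.int8)
    return sim, InteractionMatrix([f"d{j}" for j in range(n_drugs)], ids, x)


class TestKernelKNN:
    def test_weighted_vote_example(self):
        sim = sim_from([[1.0, 0.9, 0.1], [0.9, 1.0, 0.0], [0.1, 0.0, 1.0]])
        train = InteractionMatrix(["d"], ["r1", "r2"], np.array([[1, 0]]))
        scores = kernel_knn_scores(train, sim, 2, ["r0"])
        assert scores.scores[0, 0] == pytest.approx(0.9)

    def test_unanimous_neighbors_saturate_the_score(self):
        sim = sim_from([[1.0, 0.7, 0.2], [0.7, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ones = InteractionMatrix(["d"], ["r1", "r2"], np.array([[1, 1]]))
        zeros = InteractionMatrix(["d"], ["r1", "r2"], np.array([[0, 0]]))
        assert kernel_knn_scores(ones, sim, 2, ["r0"]).scores[0, 0] == 1.0
        assert kernel_knn_scores(zeros, sim, 2, ["r0"]).scores[0, 0] == 0.0

    def test_k_larger_than_training_set_uses_all(self):
        sim = sim_from([[1.0, 0.5, 0.4], [0.5, 1.0, 0.3], [0.4, 0.3, 1.0]])
        train = InteractionMatrix(["d"], ["r1", "r2"], np.array([[1, 0]]))
        a = kernel_knn_scores(train, sim, 2, ["r0"]).scores
        b = kernel_knn_scores(train, sim, 99, ["r0"]).scores
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_denominator_scores_zero(self):
        sim = sim_from([[1.0, -0.5, -0.5], [-0.5, 1.0, 0.0], [-0.5, 0.0, 1.0]])
        train = InteractionMatrix(["d"], ["r1", "r2"], np.array([[1, 1]]))
        assert kernel_knn_scores(train, sim, 2, ["r0"]).scores[0, 0] == 0.0

    def test_invalid_k_and_empty_training_set(self):
        sim, x = random_instance(np.random.default_rng(0), 4, 1)
        train = x.subset_reactions(x.reaction_ids[1:])
        with pytest.raises(ValidationError):
            kernel_knn_scores(train, sim, 0, [x.reaction_ids[0]])
        empty = x.subset_reactions([])
        with pytest.raises(ValidationError):
            kernel_knn_scores(empty, sim, 1, [x.reaction_ids[0]])

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n = int(rng.integers(3, 21))
            d = int(rng.integers(1, 6))
            sim, x = random_instance(rng, n, d)
            query = x.reaction_ids[int(rng.integers(n))]
            train_ids = [r for r in x.reaction_ids if r != query]
            train = x.subset_reactions(train_ids)
            for k in range(1, n):
                got = kernel_knn_scores(train, sim, k, [query]).scores[:, 0]
                qi = sim.ids.index(query)
                sims = {r: sim.values[qi, sim.ids.index(r)] for r in train_ids}
                labels = {r: train.x[:, train_ids.index(r)] for r in train_ids}
                np.testing.assert_allclose(got, brute_force_kernel_knn(labels, sims, k),
                                           atol=1e-12)

    def test_invariant_to_positive_rescaling_of_similarities(self):
        rng = np.random.default_rng(8)
        sim, x = random_instance(rng, 8, 3)
        train = x.subset_reactions(x.reaction_ids[1:])
        query = [x.reaction_ids[0]]
        base = kernel_knn_scores(train, sim, 4, query).scores
        scaled = SimilarityMatrix(sim.ids, sim.values * 7.25)
        np.testing.assert_allclose(
            kernel_knn_scores(train, scaled, 4, query).scores, base, atol=1e-12)

    def test_equal_similarities_reduce_kernel_knn_to_plain_knn(self):
        ids = [f"r{i}" for i in range(6)]
        vals = np.full((6, 6), 0.5)
        np.fill_diagonal(vals, 1.0)
        sim = SimilarityMatrix(ids, vals)
        rng = np.random.default_rng(3)
        x = InteractionMatrix(["d1", "d2"], ids,
                              rng.integers(0, 2, size=(2, 6)).astype(np.int8))
        train = x.subset_reactions(ids[1:])
        kk = kernel_knn_scores(train, sim, 3, [ids[0]]).scores
        plain = baseline_scores(train, sim, "knn", 3, [ids[0]]).scores
        np.testing.assert_allclose(kk, plain, atol=1e-12)


class TestBaselines:
    def test_nearest_profile_copies_the_nearest_label_row(self):
        sim = sim_from([[1.0, 0.9, 0.2], [0.9, 1.0, 0.1], [0.2, 0.1, 1.0]])
        train = InteractionMatrix(["d1", "d2", "d3"], ["r1", "r2"],
                                  np.array([[1, 0], [0, 1], [1, 1]]))
        scores = baseline_scores(train, sim, "nearest_profile", 5, ["r0"])
        np.testing.assert_array_equal(scores.scores[:, 0], [1, 0, 1])

    def test_unweighted_knn_is_the_mean_of_neighbor_labels(self):
        sim = sim_from([[1.0, 0.9, 0.8, 0.7], [0.9, 1, 0, 0],
                        [0.8, 0, 1, 0], [0.7, 0, 0, 1]])
        train = InteractionMatrix(["d"], ["r1", "r2", "r3"], np.array([[1, 1, 0]]))
        scores = baseline_scores(train, sim, "knn", 3, ["r0"])
        assert scores.scores[0, 0] == pytest.approx(2 / 3)

    def test_tie_for_nearest_resolves_to_lowest_reaction_id(self):
        ids = ["q", "ra", "rb"]
        vals = np.array([[1.0, 0.6, 0.6], [0.6, 1.0, 0.0], [0.6, 0.0, 1.0]])
        sim = SimilarityMatrix(ids, vals)
        train = InteractionMatrix(["d"], ["rb", "ra"], np.array([[1, 0]]))
        scores = baseline_scores(train, sim, "nearest_profile", 1, ["q"])
        # exhaustive argmax with the same (-sim, id) key picks "ra"
        best = min(["ra", "rb"], key=lambda r: (-0.6, r))
        assert best == "ra"
        assert scores.scores[0, 0] == 0.0


class TestAUC:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [([0.9, 0.8, 0.1], [1, 1, 0], 1.0),
         ([0.1, 0.9], [1, 0], 0.0),
         ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5)],
    )
    def test_known_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            auc([0.1, 0.2], [1, 1])

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            n = int(rng.integers(2, 13))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 1)  # coarse grid forces ties
            assert auc(scores, labels) == pytest.approx(pair_count_auc(scores, labels))

    def test_matches_sklearn_roc_auc(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        scores = rng.uniform(size=50)
        assert auc(scores, labels) == pytest.approx(
            sklearn_metrics.roc_auc_score(labels, scores))


class TestCrossValidation:
    def test_identical_seed_gives_bit_identical_reports(self):
        rng = np.random.default_rng(5)
        sim, x = random_instance(rng, 12, 3)
        cfg = CVConfig(folds=4, repeats=3, k=3, seed=99)
        a = cross_validate(x, sim, cfg)
        b = cross_validate(x, sim, cfg)
        assert a.auc_per_repeat == b.auc_per_repeat
        assert a.fold_assignments == b.fold_assignments

    def test_different_seeds_shuffle_folds(self):
        rng = np.random.default_rng(6)
        sim, x = random_instance(rng, 12, 3)
        a = cross_validate(x, sim, CVConfig(folds=4, repeats=1, k=3, seed=1))
        b = cross_validate(x, sim, CVConfig(folds=4, repeats=1, k=3, seed=2))
        assert a.fold_assignments != b.fold_assignments

    def test_report_shape_and_range(self):
        rng = np.random.default_rng(7)
        sim, x = random_instance(rng, 10, 2)
        rep = cross_validate(x, sim, CVConfig(folds=5, repeats=4, k=2, seed=0))
        assert len(rep.auc_per_repeat) == 4
        assert all(0.0 <= a <= 1.0 for a in rep.auc_per_repeat)
        assert rep.mean_auc == pytest.approx(np.mean(rep.auc_per_repeat))

    def test_too_few_reactions_for_folds_is_error(self):
        rng = np.random.default_rng(8)
        sim, x = random_instance(rng, 5, 2)
        with pytest.raises(ValidationError):
            cross_validate(x, sim, CVConfig(folds=10, repeats=1, k=1, seed=0))


class TestLOOCV:
    def test_two_reactions_use_each_other_as_training(self):
        sim = sim_from([[1.0, 0.8], [0.8, 1.0]])
        x = InteractionMatrix(["d"], ["r0", "r1"], np.array([[1, 0]]))
        report, pooled = loocv(x, sim, k=1, cutoff=0.35)
        # r1's only neighbor is r0 (label 1) -> score 1; r0's neighbor r1 -> 0
        assert pooled == 0.0
        assert set(report["reaction_id"]) == {"r1"}

    def test_agrees_with_nfold_cross_validation(self):
        rng = np.random.default_rng(9)
        sim, x = random_instance(rng, 9, 3)
        _, pooled = loocv(x, sim, k=4)
        cfg = CVConfig(folds=len(x.reaction_ids), repeats=1, k=4, seed=0)
        rep = cross_validate(x, sim, cfg)
        assert pooled == pytest.approx(rep.auc_per_repeat[0])

    def test_default_report_cutoff(self):
        sim = sim_from([[1.0, 0.5], [0.5, 1.0]])
        x = InteractionMatrix(["d1", "d2"], ["r0", "r1"],
                              np.array([[1, 1], [0, 0]]))
        report, _ = loocv(x, sim, k=1)
        assert set(report["drug_id"]) == {"d1"}
        assert (report["association_score"] > 0.35).all()


class TestGridSearch:
    def test_endpoint_cells_equal_standalone_runs(self):
        rng = np.random.default_rng(10)
        s_rf, x = random_instance(rng, 10, 3)
        rs_vals = np.abs(s_rf.values) ** 0.5
        rs_vals = (rs_vals + rs_vals.T) / 2
        np.fill_diagonal(rs_vals, 1.0)
        s_rs = SimilarityMatrix(list(s_rf.ids), rs_vals, "structure_max")
        cfg = CVConfig(folds=5, repeats=2, seed=4)
        grid = grid_search(x, s_rf, s_rs, [1, 3], [0.0, 1.0], cfg)
        assert grid.shape == (2, 2)
        from dataclasses import replace
        for i, k in enumerate([1, 3]):
            a = cross_validate(x, s_rs, replace(cfg, k=k, lam=0.0)).mean_auc
            b = cross_validate(x, s_rf, replace(cfg, k=k, lam=1.0)).mean_auc
            assert grid.iloc[i, 0] == pytest.approx(a)
            assert grid.iloc[i, 1] == pytest.approx(b)


class TestCompareAUC:
    def test_symmetry(self):
        a = [0.8, 0.82, 0.79, 0.81]
        b = [0.7, 0.72, 0.69, 0.71]
        assert compare_auc(a, b) == pytest.approx(compare_auc(b, a))

    def test_large_shift_gives_tiny_p(self):
        rng = np.random.default_rng(11)
        b = rng.normal(0.5, 0.01, size=20)
        a = b + 0.3
        assert compare_auc(list(a), list(b)) < 1e-10

    def test_matches_textbook_formula(self):
        a = [0.81, 0.84, 0.79, 0.86, 0.82]
        b = [0.75, 0.78, 0.74, 0.77]
        assert compare_auc(a, b) == pytest.approx(two_sample_t_pvalue(a, b))

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(ValidationError):
            compare_auc([0.5], [0.6, 0.7])
        with pytest.raises(UndefinedStatisticError):
            compare_auc([0.5, 0.5], [0.6, 0.6])
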