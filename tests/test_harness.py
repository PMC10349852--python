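"""LOO evaluation, algorithm comparison, feature selection, importances, OOS."""

import numpy as np
import pytest

from regiosel import (
    GeneratorConfig,
    PairDataset,
    compare_algorithms,
    feature_importance,
    generate_synthetic_dataset,
    greedy_feature_selection,
    loo_evaluate,
    oos_evaluate,
    registry_names,
)
from regiosel.harness import build_model


def _linear_dataset(n=60, p=5, signal_col=2, sigma=0.0, seed=0, n_arenes=12):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    y = 2.0 * X[:, signal_col] + (rng.normal(0, sigma, n) if sigma else 0.0)
    return PairDataset(
        X=X, y=y,
        arene_ids=[f"m{i % n_arenes}" for i in range(n)],
        feature_names=tuple(f"f{j}" for j in range(p)),
    )


class TestLooEvaluate:
    def test_ridge_recovers_noiseless_linear_map(self):
        rep = loo_evaluate(_linear_dataset(), "ridge")
        assert rep.pearson_r >= 0.999
        assert rep.mae <= 1e-6

    def test_pure_noise_targets_give_no_correlation(self):
        """Null simulation: |LOO R| stays small in seed-averaged expectation."""
        rs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            data = PairDataset(
                X=rng.normal(size=(200, 6)),
                y=rng.normal(size=200),
                arene_ids=[f"m{i % 40}" for i in range(200)],
                feature_names=tuple(f"f{j}" for j in range(6)),
            )
            rs.append(abs(loo_evaluate(data, "ridge").pearson_r))
        assert np.mean(rs) < 0.3

    def test_constant_targets_flagged_nan_r(self):
        data = _linear_dataset()
        data.y[:] = 1.5
        rep = loo_evaluate(data, "extra_trees")
        assert np.isnan(rep.pearson_r)
        assert "pearson_undefined" in rep.flags
        assert rep.mae == pytest.approx(0.0, abs=1e-12)

    def test_unknown_algorithm_registry_error(self):
        with pytest.raises(KeyError, match="registry"):
            loo_evaluate(_linear_dataset(), "deep_net")

    def test_requires_three_rows(self):
        with pytest.raises(ValueError, match="at least 3"):
            loo_evaluate(_linear_dataset(n=2, n_arenes=2), "ridge")

    def test_grouped_mode_excludes_whole_arene(self):
        """Grouped LOO must not train on any pair sharing the fold's arene:
        with a target that is an exact function of arene id, per-pair LOO can
        cheat but grouped LOO cannot."""
        rng = np.random.default_rng(1)
        n_arenes = 10
        X = rng.normal(size=(40, 3))
        arene_effect = rng.normal(0, 2.0, n_arenes)
        ids = [i % n_arenes for i in range(40)]
        data = PairDataset(
            X=X, y=np.array([arene_effect[i] for i in ids]),
            arene_ids=[f"m{i}" for i in ids],
            feature_names=("f0", "f1", "f2"),
        )
        per_pair = loo_evaluate(data, "knn", mode="pair")
        grouped = loo_evaluate(data, "knn", mode="arene")
        # features carry no signal, so honest grouped error exceeds the
        # leaky per-pair error (the held-out arene's rows are memorizable)
        assert grouped.mae > per_pair.mae

    def test_reports_are_reproducible(self):
        data, _ = generate_synthetic_dataset(GeneratorConfig(n_pairs=40, seed=5))
        a = loo_evaluate(data, "gradient_boosting", seed=3)
        b = loo_evaluate(data, "gradient_boosting", seed=3)
        assert a.config_hash == b.config_hash
        np.testing.assert_array_equal(a.predictions, b.predictions)
        assert a.pearson_r == b.pearson_r


class TestCompareAlgorithms:
    def test_two_algorithms_sorted_by_r(self):
        reports = compare_algorithms(_linear_dataset(sigma=0.1),
                                     ["extra_trees", "ridge"])
        assert len(reports) == 2
        assert reports[0].pearson_r >= reports[1].pearson_r
        assert reports[0].algorithm == "ridge"

    def test_tree_friendly_benchmark_prefers_extra_trees(self):
        """Threshold-interaction ground truth: the tree ensemble must beat
        the linear baseline."""
        data, _ = generate_synthetic_dataset(
            GeneratorConfig(n_pairs=100, seed=2, mechanism="tree_friendly",
                            noise_sigma=0.1))
        reports = {r.algorithm: r for r in
                   compare_algorithms(data, ["extra_trees", "ridge"], seed=0)}
        assert reports["extra_trees"].pearson_r > reports["ridge"].pearson_r

    def test_registry_covers_required_families(self):
        names = registry_names()
        assert {"extra_trees", "random_forest", "gradient_boosting",
                "svr", "knn", "ridge"} <= set(names)

    def test_same_seed_identical_reports(self):
        data = _linear_dataset(sigma=0.3)
        a = compare_algorithms(data, ["extra_trees", "svr"], seed=9)
        b = compare_algorithms(data, ["extra_trees", "svr"], seed=9)
        assert [(r.algorithm, r.pearson_r, r.mae) for r in a] \
            == [(r.algorithm, r.pearson_r, r.mae) for r in b]


class TestGreedySelection:
    def test_first_selected_feature_is_the_signal(self):
        data = _linear_dataset(n=50, p=6, signal_col=4, sigma=0.05)
        subset, trajectory = greedy_feature_selection(data, "ridge")
        assert subset[0] == "f4"
        rs = [t.pearson_r for t in trajectory]
        assert all(b > a for a, b in zip(rs, rs[1:]))  # non-decreasing by construction

    def test_noise_features_stay_out(self):
        data = _linear_dataset(n=80, p=8, signal_col=0, sigma=0.02, seed=3)
        subset, _ = greedy_feature_selection(data, "ridge", tolerance=1e-3)
        assert "f0" in subset
        assert len(subset) <= 3  # pure-noise columns bring no 1e-3 R gain

    def test_needs_at_least_two_features(self):
        data = _linear_dataset(p=1, signal_col=0)
        with pytest.raises(ValueError, match="2 features"):
            greedy_feature_selection(data, "ridge")


class TestFeatureImportance:
    def test_dominant_fukui_feature_ranks_first(self):
        """Ground truth carried by the reacting site's f-: that column must
        top the impurity ranking."""
        cfg = GeneratorConfig(n_pairs=120, seed=0,
                              weights={"fukui_minus": 30.0}, redox_coupling=0.0)
        data, _ = generate_synthetic_dataset(cfg)
        ranked = feature_importance(data, "extra_trees", seed=0)
        assert ranked[0][0].endswith("fukui_minus")

    def test_impurity_importances_normalized(self):
        data = _linear_dataset(sigma=0.2)
        ranked = feature_importance(data, "extra_trees")
        total = sum(v for _, v in ranked)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for _, v in ranked)

    def test_all_noise_importances_flat(self):
        rng = np.random.default_rng(4)
        data = PairDataset(
            X=rng.normal(size=(150, 8)), y=rng.normal(size=150),
            arene_ids=[f"m{i % 30}" for i in range(150)],
            feature_names=tuple(f"f{j}" for j in range(8)),
        )
        ranked = feature_importance(data, "extra_trees", seed=0)
        values = [v for _, v in ranked]
        assert max(values) < 3 * np.median(values)

    def test_permutation_importance_finds_signal(self):
        data = _linear_dataset(n=80, p=5, signal_col=1, sigma=0.05)
        ranked = feature_importance(data, "svr", method="permutation", seed=0)
        assert ranked[0][0] == "f1"
        assert all(v >= 0 for _, v in ranked)

    def test_impurity_on_non_tree_model_rejected(self):
        with pytest.raises(ValueError, match="tree"):
            feature_importance(_linear_dataset(), "svr", method="impurity")


class TestOosEvaluate:
    def test_partition_is_disjoint_and_complete(self):
        data, _ = generate_synthetic_dataset(GeneratorConfig(n_pairs=60, seed=7))
        holdout = sorted(set(data.arene_ids))[:3]
        rep = oos_evaluate(data, holdout, "ridge")
        assert set(rep.test_arenes) == set(holdout) & set(data.arene_ids)
        assert not set(rep.train_arenes) & set(rep.test_arenes)
        assert set(rep.train_arenes) | set(rep.test_arenes) == set(data.arene_ids)
        n_test = sum(a in holdout for a in data.arene_ids)
        assert rep.n_rows == n_test

    def test_empty_holdout_flagged(self):
        data = _linear_dataset()
        with pytest.warns(UserWarning, match="no pairs"):
            rep = oos_evaluate(data, ["not_an_arene"], "ridge")
        assert rep.n_rows == 0
        assert "empty_holdout" in rep.flags

    def test_holdout_of_everything_rejected(self):
        data = _linear_dataset()
        with pytest.raises(ValueError, match="every arene"):
            oos_evaluate(data, sorted(set(data.arene_ids)), "ridge")

    def test_heldout_mae_comparable_to_in_sample(self):
        """A held-out arene from the same generator should be predicted
        roughly as well as in-sample (within 2x MAE, seed-median)."""
        ratios = []
        for seed in range(8):
            data, _ = generate_synthetic_dataset(
                GeneratorConfig(n_pairs=80, seed=seed))
            arene = sorted(set(data.arene_ids))[0]
            oos = oos_evaluate(data, [arene], "ridge", seed=seed)
            loo = loo_evaluate(data, "ridge", seed=seed)
            ratios.append(oos.mae / loo.mae)
        assert np.median(ratios) < 2.0


def test_model_registry_seeds_are_applied():
    a = build_model("extra_trees", seed=1)
    b = build_model("extra_trees", seed=2)
    assert a.get_params()["random_state"] != b.get_params()["random_state"]
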