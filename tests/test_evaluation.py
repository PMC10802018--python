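"""Split protocol, metric definitions, and pipeline composition."""

import numpy as np
import pytest

from mosegcn import PipelineConfig, run_experiment, single_omics_ablation
from mosegcn.evaluation import build_representation, compute_metrics, make_splits
from mosegcn.omics_data import LabelSet, MultiOmicsDataset, OmicsMatrix, UNLABELED
from mosegcn.synthetic_data import SyntheticSpec, generate_multiomics

FAST = dict(
    encoder={"latent_dim": 16, "epochs": 60, "learning_rate": 5e-3},
    segcn={"epochs": 80, "hidden_dim": 16},
    snf_k_neighbors=10,
)


def _labels(n_per_class, n_classes=2):
    ids, y = [], []
    for c in range(n_classes):
        for i in range(n_per_class):
            ids.append(f"c{c}s{i}")
            y.append(c)
    return LabelSet(sample_ids=ids, y=np.array(y), class_names=tuple(map(str, range(n_classes))))


class TestMakeSplits:
    def test_seven_three_arithmetic(self):
        plan = make_splits(_labels(10), n_repeats=5, seed=0)
        for train, test in plan.splits:
            assert len(train) == 14 and len(test) == 6

    def test_same_seed_same_plan(self):
        p1 = make_splits(_labels(10), seed=3)
        p2 = make_splits(_labels(10), seed=3)
        assert p1.splits == p2.splits

    def test_partition_contract(self):
        labels = _labels(10, 3)
        plan = make_splits(labels, n_repeats=30, seed=1)
        assert plan.n_repeats == 30 and len(plan.splits) == 30
        all_ids = set(np.array(labels.sample_ids)[labels.labeled_mask])
        for train, test in plan.splits:
            assert set(train) | set(test) == all_ids
            assert set(train) & set(test) == set()

    def test_stratification_within_one_sample(self):
        labels = _labels(10, 3)
        plan = make_splits(labels, n_repeats=10, seed=2)
        for train, _ in plan.splits:
            for c in range(3):
                n_train_c = sum(1 for s in train if s.startswith(f"c{c}"))
                assert abs(n_train_c - 7) <= 1

    def test_singleton_class_rejected(self):
        ids = ["a", "b", "c"]
        labels = LabelSet(sample_ids=ids, y=np.array([0, 0, 1]), class_names=("x", "y"))
        with pytest.raises(ValueError, match="fewer than 2"):
            make_splits(labels)


class TestComputeMetrics:
    def test_textbook_confusion_counts(self):
        # TP=3, FP=1, FN=1, TN=5
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        row = compute_metrics(y_true, y_pred, task="binary")
        assert row["acc"] == pytest.approx(0.8)
        assert row["precision"] == pytest.approx(0.75)
        assert row["recall"] == pytest.approx(0.75)
        assert row["f1"] == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        row = compute_metrics(y, y, task="multiclass")
        assert all(row[k] == 1.0 for k in ("acc", "precision", "recall", "f1_weighted", "f1_macro"))

    def test_equal_supports_make_macro_equal_weighted(self):
        y_true = np.array([0, 0, 1, 1, 2, 2])
        y_pred = np.array([0, 0, 1, 2, 1, 1])
        row = compute_metrics(y_true, y_pred, task="multiclass")
        # hand-computed per-class F1 from the confusion counts
        f1s = []
        for c in range(3):
            tp = int(((y_true == c) & (y_pred == c)).sum())
            fp = int(((y_true != c) & (y_pred == c)).sum())
            fn = int(((y_true == c) & (y_pred != c)).sum())
            f1s.append(2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0)
        assert row["f1_macro"] == pytest.approx(np.mean(f1s))
        # equal class supports: the weighted average collapses to the macro one
        assert row["f1_weighted"] == pytest.approx(row["f1_macro"])

    def test_matches_confusion_matrix_oracle(self, rng):
        for _ in range(50):
            n = rng.integers(10, 40)
            y_true = rng.integers(0, 2, size=n)
            if len(np.unique(y_true)) < 2:
                continue
            y_pred = rng.integers(0, 2, size=n)
            row = compute_metrics(y_true, y_pred, task="binary")
            tp = int(((y_true == 1) & (y_pred == 1)).sum())
            fp = int(((y_true == 0) & (y_pred == 1)).sum())
            fn = int(((y_true == 1) & (y_pred == 0)).sum())
            tn = int(((y_true == 0) & (y_pred == 0)).sum())
            assert row["acc"] == pytest.approx((tp + tn) / n)
            assert row["precision"] == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert row["recall"] == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            p, r = row["precision"], row["recall"]
            assert row["f1"] == pytest.approx(2 * p * r / (p + r) if p + r else 0.0)

    def test_auc_matches_rank_statistic(self, rng):
        y = rng.integers(0, 2, size=30)
        y[:2] = [0, 1]
        scores = rng.random(30)
        probs = np.column_stack([1 - scores, scores])
        row = compute_metrics(y, (scores > 0.5).astype(int), probs, task="binary")
        pos = scores[y == 1]
        neg = scores[y == 0]
        pairs = [(1.0 if p > q else 0.5 if p == q else 0.0) for p in pos for q in neg]
        assert row["auc"] == pytest.approx(np.mean(pairs), abs=1e-10)

    def test_auc_missing_for_single_class(self):
        row = compute_metrics(np.ones(4, dtype=int), np.ones(4, dtype=int),
                              np.tile([0.3, 0.7], (4, 1)), task="binary")
        assert np.isnan(row["auc"])


@pytest.fixture(scope="module")
def medium_dataset():
    spec = SyntheticSpec(n_samples=90, n_classes=3, feature_counts=(30, 24),
                         informative_per_omics=5, effect_size=4.0,
                         labeled_fraction=0.4, seed=4)
    return generate_multiomics(spec)


class TestRunExperiment:
    def test_single_repeat_equals_manual_composition(self, medium_dataset):
        from mosegcn import segcn

        ds, _ = medium_dataset
        cfg = PipelineConfig(n_repeats=1, seed=7, **FAST)
        result = run_experiment(ds, cfg)

        # manual pipeline with the identical seed derivation
        rep = build_representation(ds, cfg)
        plan = make_splits(ds.labels, 1, 0.7, 7)
        ss = np.random.SeedSequence(7)
        repeat_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
        pos = {s: i for i, s in enumerate(rep.dataset.sample_ids)}
        train_idx = np.array([pos[s] for s in plan.splits[0][0]])
        test_idx = np.array([pos[s] for s in plan.splits[0][1]])
        y_m = np.full(rep.dataset.n_samples, UNLABELED)
        y_m[train_idx] = rep.dataset.labels.y[train_idx]
        state, _ = segcn.fit(rep.features, rep.A_hat, y_m, 3,
                             segcn.SEGCNConfig(seed=repeat_seed, **cfg.segcn))
        pred, _ = segcn.predict(state, rep.A_hat, rep.features)
        np.testing.assert_array_equal(result.predictions[0]["y_pred"], pred[test_idx])

    def test_summary_is_mean_of_repeats(self, medium_dataset):
        ds, _ = medium_dataset
        result = run_experiment(ds, PipelineConfig(n_repeats=3, seed=1, **FAST))
        assert result.summary.loc["mean", "acc"] == pytest.approx(result.per_repeat["acc"].mean())
        assert len(result.per_repeat) == 3

    def test_same_seed_runs_byte_identical(self, medium_dataset):
        ds, _ = medium_dataset
        cfg = PipelineConfig(n_repeats=2, seed=9, **FAST)
        r1 = run_experiment(ds, cfg)
        r2 = run_experiment(ds, cfg)
        assert r1.per_repeat.to_csv() == r2.per_repeat.to_csv()
        for k in r1.predictions:
            assert r1.predictions[k]["y_pred"].tobytes() == r2.predictions[k]["y_pred"].tobytes()
            assert r1.predictions[k]["log"].to_csv() == r2.predictions[k]["log"].to_csv()

    def test_test_labels_are_masked_during_training(self, medium_dataset):
        ds, _ = medium_dataset
        cfg = PipelineConfig(n_repeats=2, seed=5, **FAST)
        result = run_experiment(ds, cfg)
        labeled_ids = set(np.array(ds.labels.sample_ids)[ds.labels.labeled_mask])
        for rec in result.predictions.values():
            test_ids = set(rec["test_ids"])
            assert test_ids <= labeled_ids  # test nodes come from the labeled pool
            # and are scored against their held-out truth
            assert len(rec["y_true"]) == len(rec["y_pred"])


class TestAblation:
    def test_signal_free_block_scores_lower(self):
        # omics1 carries all the signal; omics2 is pure noise
        spec = SyntheticSpec(n_samples=90, n_classes=3, feature_counts=(30, 24),
                             informative_per_omics=5, effect_size=4.0,
                             labeled_fraction=0.4, seed=8)
        ds, _ = generate_multiomics(spec)
        noise = np.random.default_rng(0).normal(size=ds.omics[1].values.shape)
        blocks = (
            ds.omics[0],
            OmicsMatrix(name="omics2", values=noise,
                        sample_ids=ds.omics[1].sample_ids,
                        feature_ids=ds.omics[1].feature_ids),
        )
        noisy = MultiOmicsDataset(omics=blocks, labels=ds.labels)
        accs = {"omics1": [], "omics2": []}
        for seed in (0, 1, 2):
            # raw features isolate the graph ablation from encoder quality
            cfg = PipelineConfig(n_repeats=1, seed=seed, gcn_features="raw",
                                 segcn={"epochs": 150, "hidden_dim": 16},
                                 encoder={"latent_dim": 16, "epochs": 5},
                                 snf_k_neighbors=10)
            res = single_omics_ablation(noisy, cfg)
            for name in accs:
                accs[name].append(res[name].summary.loc["mean", "acc"])
        assert np.mean(accs["omics1"]) > np.mean(accs["omics2"])

    def test_single_block_requires_multi_omics(self, medium_dataset):
        ds, _ = medium_dataset
        single = MultiOmicsDataset(omics=(ds.omics[0],), labels=ds.labels)
        with pytest.raises(ValueError, match="multi-omics"):
            single_omics_ablation(single, PipelineConfig())
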