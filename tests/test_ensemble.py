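"""Negative partitioning, balanced subsets, sub-model training and fusion."""

import numpy as np
import pytest

from promoter5mc import (
    Sample,
    SubModelConfig,
    build_balanced_subset,
    cross_validate,
    evaluate_ensemble,
    fuse_decision,
    fuse_score,
    load_model,
    partition_negatives,
    predict,
    predict_proba,
    save_model,
    train_ensemble,
    train_submodel,
)
from promoter5mc.exceptions import (
    IncompatibleModelError,
    TrainingError,
    ValidationError,
)
from conftest import FAST_CONFIG


class TestPartitionNegatives:
    def test_exact_division(self):
        groups = partition_negatives(np.arange(22), 11, seed=0)
        assert len(groups) == 11
        assert all(len(g) == 2 for g in groups)

    def test_near_equal_division(self):
        groups = partition_negatives(np.arange(23), 11, seed=0)
        sizes = sorted(len(g) for g in groups)
        assert sizes == [2] * 10 + [3]

    def test_disjoint_and_covering(self, rng):
        ids = rng.choice(10_000, size=503, replace=False)
        groups = partition_negatives(ids, 7, seed=1)
        merged = np.concatenate(groups)
        assert len(merged) == len(ids)
        assert set(merged.tolist()) == set(ids.tolist())

    def test_deterministic(self):
        a = partition_negatives(np.arange(50), 5, seed=9)
        b = partition_negatives(np.arange(50), 5, seed=9)
        assert all((x == y).all() for x, y in zip(a, b))

    def test_too_many_groups(self):
        with pytest.raises(ValidationError):
            partition_negatives(np.arange(5), 11, seed=0)


def _mk(n, label):
    return [Sample("AACAA", 2, label=label) for _ in range(n)]


class TestBuildBalancedSubset:
    def test_equal_sides(self):
        subset = build_balanced_subset(_mk(100, 0), _mk(100, 1))
        labels = [s.label for s in subset]
        assert len(subset) == 200 and labels.count(0) == labels.count(1) == 100

    def test_larger_negatives_downsampled(self):
        subset = build_balanced_subset(_mk(105, 0), _mk(100, 1), seed=0)
        labels = [s.label for s in subset]
        assert len(subset) == 200 and labels.count(0) == labels.count(1) == 100

    def test_larger_positives_downsampled(self):
        subset = build_balanced_subset(_mk(50, 0), _mk(70, 1), seed=0)
        labels = [s.label for s in subset]
        assert labels.count(0) == labels.count(1) == 50

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            build_balanced_subset([], _mk(3, 1))


class TestFuseDecision:
    @pytest.mark.parametrize(
        "scores,fusion,expected",
        [
            ([0.9] * 11, "unanimous", 1),
            ([0.9] * 10 + [0.4], "unanimous", 0),
            ([0.1] * 11, "unanimous", 0),
            ([0.1] * 11, "majority", 0),
            ([0.9] * 6 + [0.1] * 5, "majority", 1),
            ([0.9] * 5 + [0.1] * 6, "majority", 0),
        ],
    )
    def test_examples(self, scores, fusion, expected):
        assert fuse_decision(scores, fusion) == expected

    def test_unanimous_truth_table_exhaustive(self):
        """Over all 2^11 threshold-exceedance patterns the unanimous rule is
        positive iff every sub-model exceeds the threshold."""
        for pattern in range(2**11):
            bits = [(pattern >> i) & 1 for i in range(11)]
            scores = [0.9 if b else 0.1 for b in bits]
            assert fuse_decision(scores, "unanimous") == int(all(bits))
            assert fuse_decision(scores, "majority") == int(sum(bits) > 5.5)

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            fuse_decision([], "unanimous")

    def test_unknown_rule(self):
        with pytest.raises(ValidationError):
            fuse_decision([0.5], "median")


class TestFuseScore:
    def test_examples(self):
        assert fuse_score([0.9, 0.8, 0.7], "min") == pytest.approx(0.7)
        assert fuse_score([0.9, 0.8, 0.7], "mean") == pytest.approx(0.8)

    def test_min_fusion_threshold_equivalence(self, rng):
        """Thresholding the min-fused score reproduces the unanimous decision
        for random score vectors and thresholds."""
        for _ in range(500):
            k = int(rng.integers(1, 15))
            scores = rng.random(k)
            t = float(rng.random())
            assert (fuse_score(scores, "min") > t) == bool(
                fuse_decision(scores, "unanimous", t)
            )

    def test_empty_raises(self):
        with pytest.raises(ValidationError):
            fuse_score([], "min")


class TestTrainSubmodel:
    def _separable(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        y = (X[:, 0] > 0).astype(int)
        X[:, 0] += np.where(y == 1, 3.0, -3.0)
        return X, y

    def test_separable_toy_high_accuracy(self):
        X, y = self._separable()
        clf = train_submodel(
            X, y,
            SubModelConfig(hidden_layers=[16, 16], epochs=100, batch_size=32,
                           learning_rate=1e-2, seed=0),
        )
        assert (clf.predict(X) == y).mean() >= 0.99

    def test_same_seed_identical_predictions(self):
        X, y = self._separable()
        cfg = SubModelConfig(hidden_layers=[8, 8], epochs=20, seed=4)
        probe = np.random.default_rng(1).normal(size=(30, 2))
        p1 = train_submodel(X, y, cfg).predict_proba(probe)
        p2 = train_submodel(X, y, cfg).predict_proba(probe)
        assert (p1 == p2).all()

    def test_single_class_raises(self):
        X, _ = self._separable()
        with pytest.raises(TrainingError):
            train_submodel(X, np.zeros(len(X)), SubModelConfig())

    def test_nan_features_raise(self):
        X, y = self._separable()
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            train_submodel(X, y, SubModelConfig())


class TestEnsemble:
    def test_predict_proba_shape_and_range(self, small_model, small_dataset):
        scores = predict_proba(small_model, small_dataset[:25])
        assert scores.shape == (25, small_model.k)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_inference_deterministic(self, small_model, small_dataset):
        a = predict_proba(small_model, small_dataset[:10])
        b = predict_proba(small_model, small_dataset[:10])
        assert (a == b).all()

    def test_delta_mismatch_raises(self, small_model):
        with pytest.raises(ValidationError):
            predict_proba(small_model, [Sample("AACAA", 2)])

    def test_unanimity_dominance(self, small_model, small_dataset):
        """The unanimous positive set is a subset of every sub-model's
        positive set, so fused Sp >= each sub-model's Sp."""
        fused, calls, sub_scores = predict(small_model, small_dataset)
        sub_calls = sub_scores > small_model.threshold
        for j in range(small_model.k):
            assert (calls <= sub_calls[:, j].astype(int)).all()
        fused_rep, sub_reps = evaluate_ensemble(small_model, small_dataset)
        for rep in sub_reps:
            assert fused_rep.sp >= rep.sp

    def test_learns_planted_signal(self, small_model, small_dataset):
        fused_rep, _ = evaluate_ensemble(small_model, small_dataset)
        assert fused_rep.auc is not None and fused_rep.auc >= 0.9

    def test_save_load_round_trip(self, small_model, small_dataset, tmp_path):
        fused_before, _, sub_before = predict(small_model, small_dataset[:15])
        save_model(small_model, tmp_path / "bundle")
        loaded = load_model(tmp_path / "bundle")
        fused_after, _, sub_after = predict(loaded, small_dataset[:15])
        assert (sub_before == sub_after).all()
        assert (fused_before == fused_after).all()
        assert loaded.k == small_model.k
        assert loaded.encoding == small_model.encoding

    def test_truncated_bundle_raises(self, small_model, tmp_path):
        save_model(small_model, tmp_path / "bundle")
        victim = tmp_path / "bundle" / "submodel_01.joblib"
        victim.write_bytes(victim.read_bytes()[:40])
        with pytest.raises(IncompatibleModelError):
            load_model(tmp_path / "bundle")

    def test_missing_manifest_raises(self, tmp_path):
        (tmp_path / "empty").mkdir()
        with pytest.raises(IncompatibleModelError):
            load_model(tmp_path / "empty")


class TestCrossValidate:
    def _data(self):
        from promoter5mc import GeneratorConfig, generate_dataset

        return generate_dataset(
            GeneratorConfig(n_pos=36, n_neg=180, delta=4, effect=0.9, seed=5)
        )

    def test_deterministic_given_seed(self):
        data = self._data()
        kw = dict(folds=3, config=FAST_CONFIG, seed=21, k=3)
        a = cross_validate(data, **kw)
        b = cross_validate(data, **kw)
        assert a.fused == b.fused
        assert a.submodels == b.submodels

    def test_counts_cover_dataset(self):
        data = self._data()
        res = cross_validate(data, folds=3, config=FAST_CONFIG, seed=3, k=3)
        # pooled over folds, every sample appears in exactly one test fold
        assert res.fused.n_pos == 36 and res.fused.n_neg == 180

    def test_too_few_per_class_raises(self):
        data = _mk(3, 1) + _mk(30, 0)
        from promoter5mc.exceptions import StratificationError

        with pytest.raises(StratificationError):
            cross_validate(data, folds=5, k=2)
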