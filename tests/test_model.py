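"""Scaling, training, and nested cross-validation of the fusion classifier."""

import numpy as np
import pandas as pd
import pytest

from neurofuse import model as mm
from neurofuse import nn
from neurofuse.evaluation import auc_roc
from neurofuse.features import FeatureTable


class TestScaleFeatures:
    def test_median_iqr_hand_example(self):
        train = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        scaled, scaler = mm.scale_features(train)
        assert scaler.center[0] == 3.0 and scaler.scale[0] == 2.0
        assert scaled[-1, 0] == pytest.approx(1.0)

    def test_constant_column_centred_unscaled(self):
        train = np.full((6, 1), 7.0)
        scaled, _ = mm.scale_features(train)
        np.testing.assert_array_equal(scaled, 0.0)

    def test_train_map_applied_to_test_leaves_test_uncentred(self):
        rng = np.random.default_rng(0)
        train = rng.normal(0, 1, (50, 3))
        test = rng.normal(2, 1, (50, 3))
        _, scaled_test, _ = mm.scale_features(train, test)
        assert np.abs(np.median(scaled_test, axis=0)).min() > 0.5


def toy_blocks(n=200, seed=1, separable=True):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 2))
    y = (X @ np.array([1.0, -1.0]) > 0).astype(float)
    if not separable:
        y = rng.permutation(y)
    return {"structural": X}, y


class TestTraining:
    spec = mm.ModelSpec(frnn_widths={"structural": [16, 8]}, cnn_widths=(16,))

    def test_separable_toy_reaches_high_training_auc(self):
        blocks, y = toy_blocks()
        tm = mm.train_model(self.spec, mm.TrainConfig(epochs=150, seed=0), blocks, y)
        assert auc_roc(tm.predict_proba(blocks), y).auc > 0.95

    def test_permuted_labels_stay_at_chance(self):
        aucs = []
        for seed in range(10):
            blocks, y = toy_blocks(seed=seed, separable=False)
            tr = {k: v[:150] for k, v in blocks.items()}
            te = {k: v[150:] for k, v in blocks.items()}
            tm = mm.train_model(self.spec, mm.TrainConfig(epochs=30, seed=seed),
                                tr, y[:150])
            aucs.append(auc_roc(tm.predict_proba(te), y[150:]).auc)
        assert 0.4 < np.mean(aucs) < 0.6

    def test_training_is_deterministic_given_seed(self):
        blocks, y = toy_blocks()
        cfg = mm.TrainConfig(epochs=20, seed=3)
        a = mm.train_model(self.spec, cfg, blocks, y)
        b = mm.train_model(self.spec, cfg, blocks, y)
        np.testing.assert_array_equal(a.predict_proba(blocks), b.predict_proba(blocks))
        assert a.loss_history == b.loss_history

    def test_loss_propagates_into_reduction_network(self):
        blocks, y = toy_blocks()
        net = nn.JointFusionNet([2], [[16, 8]], [16], seed=0)
        # bias of a Dense feeding BatchNorm has exactly zero gradient (the
        # batch mean removes it), so inspect the weight matrices
        weights = [l.W for l in net.frnns[0].layers if isinstance(l, nn.Dense)]
        before = [w.value.copy() for w in weights]
        nn.train(net, [blocks["structural"]], y, epochs=3, seed=0)
        assert all(not np.allclose(b, w.value) for b, w in zip(before, weights))

    def test_frozen_reduction_network_underperforms_joint_training(self):
        # complementary nonlinear signal; freezing the FR-NNs removes co-learning
        deltas = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            X1 = rng.normal(size=(300, 6))
            X2 = rng.normal(size=(300, 6))
            y = ((X1[:, 0] * X1[:, 1] + X2[:, 0] * X2[:, 1]) > 0).astype(float)
            spec = mm.ModelSpec(
                frnn_widths={"structural": [16, 8], "functional": [16, 8]},
                cnn_widths=(16,))
            tr = {"structural": X1[:240], "functional": X2[:240]}
            te = {"structural": X1[240:], "functional": X2[240:]}
            cfg = mm.TrainConfig(epochs=60, seed=seed)
            joint = mm.train_model(spec, cfg, tr, y[:240])
            frozen = mm.train_model(spec, cfg, tr, y[:240], freeze_frnn=True)
            deltas.append(auc_roc(joint.predict_proba(te), y[240:]).auc
                          - auc_roc(frozen.predict_proba(te), y[240:]).auc)
        assert np.median(deltas) > 0

    def test_non_finite_loss_aborts_with_diagnostics(self):
        blocks, y = toy_blocks()
        bad = {"structural": blocks["structural"].copy()}
        bad["structural"][0, 0] = np.inf  # broken upstream scaling
        with pytest.raises(RuntimeError, match="loss"):
            mm.train_model(self.spec, mm.TrainConfig(epochs=5, seed=0), bad, y)


class TestNestedCV:
    def make_table(self, n=120, seed=2, signal=True):
        rng = np.random.default_rng(seed)
        Xs = rng.normal(size=(n, 6))
        Xf = rng.normal(size=(n, 10))
        logits = Xs[:, 0] + Xf[:, 0] if signal else rng.normal(size=n)
        y = (logits > 0).astype(int)
        ids = [f"s{i:03d}" for i in range(n)]
        df = pd.DataFrame(np.hstack([Xs, Xf]), index=ids,
                          columns=[f"st{i}" for i in range(6)] + [f"fn{i}" for i in range(10)])
        modality = pd.Series(["structural"] * 6 + ["functional"] * 10, index=df.columns)
        dx = pd.Series(np.where(y == 1, "ASD", "TD"), index=ids)
        return FeatureTable(df, modality), dx

    spec = mm.ModelSpec(frnn_widths={"structural": [8, 4], "functional": [8, 4]},
                        cnn_widths=(8,))

    def test_outer_folds_partition_and_sizes_on_full_cohort_size(self):
        y = np.array([1] * 680 + [0] * 703)
        folds = mm.outer_fold_assignments(y, 10, seed=0)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {138, 139}
        all_idx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(all_idx, np.arange(1383))
        # stratification: per-fold positives within +-2 of the cohort rate
        for f in folds:
            assert abs(y[f].sum() - 680 / 10) <= 2

    def test_signal_cohort_beats_chance_and_audit_is_clean(self):
        table, dx = self.make_table()
        res = mm.nested_cv(table, dx, outer_k=3, inner_k=2,
                           search_space=((8,), (8, 4)), spec=self.spec,
                           config=mm.TrainConfig(epochs=40), seed=0)
        assert res.auc_mean > 0.55  # linear signal must be detected
        assert mm.audit_leakage(res) == []
        assert all(f.selected_cnn in {(8,), (8, 4)} for f in res.folds)
        assert all((0 <= f.scores).all() and (f.scores <= 1).all() for f in res.folds)

    def test_identical_seed_reproduces_fold_aucs(self):
        table, dx = self.make_table()
        kw = dict(outer_k=3, search_space=((8,),), spec=self.spec,
                  config=mm.TrainConfig(epochs=10), seed=5)
        a = mm.nested_cv(table, dx, **kw)
        b = mm.nested_cv(table, dx, **kw)
        np.testing.assert_array_equal(a.fold_aucs(), b.fold_aucs())
        assert [f.test_ids for f in a.folds] == [f.test_ids for f in b.folds]

    def test_too_small_class_is_rejected(self):
        table, dx = self.make_table(n=30)
        with pytest.raises(ValueError, match="too few"):
            mm.nested_cv(table, dx, outer_k=10, search_space=((8,),),
                         spec=self.spec, seed=0)

    def test_results_serialize(self, tmp_path):
        table, dx = self.make_table()
        res = mm.nested_cv(table, dx, outer_k=2, search_space=((8,),),
                           spec=self.spec, config=mm.TrainConfig(epochs=5), seed=1)
        res.to_json(tmp_path / "cv.json")
        res.scores_tsv(tmp_path / "scores.tsv")
        scores = pd.read_csv(tmp_path / "scores.tsv", sep="\t")
        assert set(scores["fold"]) == {0, 1}
        assert len(scores) == 120
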