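"""Expected-gradients attribution and importance normalization."""

import numpy as np
import pandas as pd
import pytest

from neurofuse import explain as ex


class LinearNet:
    """Stand-in differentiable model F(x) = w.x + c for closed-form checks."""

    def __init__(self, w, c=0.0):
        self.w = np.asarray(w, float)
        self.c = c
        self.input_dims = [len(self.w)]

    def predict_proba(self, blocks):
        return blocks[0] @ self.w + self.c

    def input_gradients(self, blocks):
        return [np.tile(self.w, (blocks[0].shape[0], 1))]


class LinearModel:
    modalities = ["structural"]

    def __init__(self, w, c=0.0):
        self.net = LinearNet(w, c)

    def predict_proba(self, blocks):
        return self.net.predict_proba([blocks[m] for m in self.modalities])


class TestGradientShap:
    def test_linear_model_matches_closed_form(self):
        rng = np.random.default_rng(0)
        w = np.array([1.5, -2.0, 0.5])
        m = LinearModel(w, c=0.3)
        x = rng.normal(size=(6, 3))
        b = rng.normal(size=(1, 3))
        phi = ex.gradient_shap(m, {"structural": x}, {"structural": b},
                               n_samples=200, seed=1)["structural"]
        exact = (x - b) * w
        assert np.max(np.abs(phi - exact) / np.maximum(np.abs(exact), 1e-12)) < 0.01

    def test_input_equal_to_baseline_gives_zero(self):
        b = np.array([[1.0, 2.0]])
        m = LinearModel([3.0, -1.0])
        phi = ex.gradient_shap(m, {"structural": b.copy()}, {"structural": b},
                               n_samples=50, seed=0)["structural"]
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_empty_background_rejected(self):
        m = LinearModel([1.0])
        with pytest.raises(ValueError, match="background"):
            ex.gradient_shap(m, {"structural": np.ones((2, 1))},
                             {"structural": np.empty((0, 1))}, seed=0)

    def test_completeness_on_trained_network(self):
        from neurofuse import model as mm
        rng = np.random.default_rng(0)
        Xs = rng.normal(size=(300, 4))
        Xf = rng.normal(size=(300, 6))
        y = (2 * Xs[:, 0] - 2 * Xf[:, 1] + 0.3 * rng.normal(size=300) > 0).astype(float)
        spec = mm.ModelSpec(frnn_widths={"structural": [32, 16], "functional": [32, 16]},
                            cnn_widths=(32,))
        tm = mm.train_model(spec, mm.TrainConfig(epochs=300, seed=0),
                            {"structural": Xs, "functional": Xf}, y)
        inp = {"structural": Xs[:20], "functional": Xf[:20]}
        bg = {"structural": Xs[50:150], "functional": Xf[50:150]}
        phi = ex.gradient_shap(tm, inp, bg, n_samples=500, seed=1)
        total = phi["structural"].sum(1) + phi["functional"].sum(1)
        expected = tm.predict_proba(inp) - tm.predict_proba(bg).mean()
        rel = np.abs(total - expected).sum() / np.abs(expected).sum()
        assert rel < 0.05


class TestImportance:
    def test_absolute_value_rule(self):
        assert ex.importance(np.array([[1.0], [-1.0]]))[0] == 1.0
        assert ex.importance(np.zeros((4, 2))).tolist() == [0.0, 0.0]

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        phi = rng.normal(size=(5, 3))
        np.testing.assert_allclose(ex.importance(phi), np.abs(phi).mean(0),
                                   atol=1e-15)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ex.importance(np.empty((0, 3)))


class TestNormalization:
    def test_symmetric_sizes_split_quarters(self):
        rng = np.random.default_rng(2)
        s = pd.Series(rng.random(10), index=[f"s{i}" for i in range(10)])
        f = pd.Series(rng.random(10), index=[f"f{i}" for i in range(10)])
        out = ex.normalize_importance(s, f)
        assert out[s.index].sum() == pytest.approx(0.25)
        assert out[f.index].sum() == pytest.approx(0.25)

    def test_published_feature_counts_give_published_shares(self):
        s = pd.Series(1.0, index=[f"s{i}" for i in range(221)])
        f = pd.Series(1.0, index=[f"f{i}" for i in range(5253)])
        out = ex.normalize_importance(s, f)
        assert out[s.index].sum() == pytest.approx(221 / 10948, abs=1e-12)
        assert out[f.index].sum() == pytest.approx(5253 / 10948, abs=1e-12)

    def test_grand_total_is_exactly_half_for_random_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            ns, nf = int(rng.integers(2, 50)), int(rng.integers(2, 50))
            s = pd.Series(rng.random(ns) + 1e-6, index=[f"s{i}" for i in range(ns)])
            f = pd.Series(rng.random(nf) + 1e-6, index=[f"f{i}" for i in range(nf)])
            assert ex.normalize_importance(s, f).sum() == pytest.approx(0.5, abs=1e-12)

    def test_uniform_scores_stay_uniform(self):
        s = pd.Series(3.7, index=[f"s{i}" for i in range(5)])
        f = pd.Series(0.2, index=[f"f{i}" for i in range(8)])
        out = ex.normalize_importance(s, f)
        assert out[s.index].nunique() == 1 and out[f.index].nunique() == 1

    def test_zero_modality_rejected(self):
        s = pd.Series(0.0, index=["s0", "s1"])
        f = pd.Series(1.0, index=["f0"])
        with pytest.raises(ValueError, match="zero"):
            ex.normalize_importance(s, f)


class TestAggregation:
    def test_identical_vectors_average_to_themselves(self):
        v = pd.Series([0.1, 0.4], index=["a", "b"])
        out = ex.aggregate_repetitions([v] * 100)
        pd.testing.assert_series_equal(out, v)

    def test_two_vector_mean(self):
        a = pd.Series([0.0, 1.0], index=["a", "b"])
        b = pd.Series([1.0, 0.0], index=["a", "b"])
        out = ex.aggregate_repetitions([a, b])
        assert out.tolist() == [0.5, 0.5]

    def test_variance_shrinks_with_repetitions(self):
        rng = np.random.default_rng(4)
        idx = [f"x{i}" for i in range(20)]
        def mean_of(k, trial):
            vs = [pd.Series(rng.random(20), index=idx) for _ in range(k)]
            return ex.aggregate_repetitions(vs)
        var1 = np.var([mean_of(1, t).iloc[0] for t in range(200)])
        var16 = np.var([mean_of(16, t).iloc[0] for t in range(200)])
        assert var16 < var1 / 8  # ~1/k scaling

    def test_inconsistent_features_rejected(self):
        a = pd.Series([1.0], index=["a"])
        b = pd.Series([1.0], index=["b"])
        with pytest.raises(ValueError, match="feature set"):
            ex.aggregate_repetitions([a, b])


class TestSelection:
    def test_one_of_one_hundred(self):
        s = pd.Series(np.arange(100.0), index=[f"x{i}" for i in range(100)])
        assert ex.select_top(s, 99) == ["x99"]

    def test_count_at_published_feature_total(self):
        rng = np.random.default_rng(5)
        s = pd.Series(rng.random(5474), index=[f"x{i}" for i in range(5474)])
        assert len(ex.select_top(s, 99)) in (54, 55)

    def test_percentile_zero_selects_all_but_minimum_ties(self):
        s = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert set(ex.select_top(s, 0)) == {"b", "c"}

    def test_percentile_validation(self):
        s = pd.Series([1.0], index=["a"])
        with pytest.raises(ValueError, match="percentile"):
            ex.select_top(s, 100)


class TestCohensD:
    def test_equal_means_give_zero(self):
        assert ex.cohens_d([1, 2, 3], [3, 2, 1]).d == 0.0

    def test_hand_computed_example(self):
        rep = ex.cohens_d([1, 2, 3], [2, 3, 4])
        assert rep.d == pytest.approx(-1.0)
        assert rep.sign == -1

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(6)
        a, t = rng.normal(1, 1, 30), rng.normal(0, 1, 30)
        assert ex.cohens_d(a, t).d == pytest.approx(-ex.cohens_d(t, a).d)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            ex.cohens_d([1.0], [1, 2])
        with pytest.raises(ValueError, match="pooled"):
            ex.cohens_d([1.0, 1.0], [2.0, 2.0])


def test_importance_table_flags_and_ranks():
    rng = np.random.default_rng(7)
    s_norm = pd.Series(rng.random(200), index=[f"x{i}" for i in range(200)])
    modality = pd.Series("functional", index=s_norm.index)
    table = ex.importance_table(s_norm, modality, percentile=99)
    assert table["selected"].sum() == len(ex.select_top(s_norm, 99))
    assert sorted(table["rank"]) == list(range(1, 201))
    assert table.index[0] == s_norm.idxmax()
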