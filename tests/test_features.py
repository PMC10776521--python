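"""Connectivity features and the structural stats reader."""

import numpy as np
import pandas as pd
import pytest

from neurofuse import features, schema
from neurofuse.features import (FCMatrix, fc_to_features, filter_regions,
                                pearson_fc, read_freesurfer_stats,
                                write_freesurfer_stats)
from neurofuse.synthetic import TimeseriesSet


def ts(data, regions=None):
    data = np.asarray(data, dtype=float)
    regions = regions or [f"r{i}" for i in range(data.shape[0])]
    return TimeseriesSet(regions=regions, data=data)


class TestPearsonFC:
    def test_identical_and_negated_series(self):
        x = np.sin(np.arange(10.0))
        fc = pearson_fc(ts([x, x, -x]))
        assert fc.values[0, 1] == pytest.approx(1.0)
        assert fc.values[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(fc.values), 1.0)

    def test_matches_bruteforce_covariance_formula(self):
        data = np.array([[1, 3, 2, 5, 4], [2, 2, 3, 1, 5], [9, 1, 4, 4, 2]], float)
        fc = pearson_fc(ts(data))
        for i in range(3):
            for j in range(3):
                xi, xj = data[i] - data[i].mean(), data[j] - data[j].mean()
                r = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert abs(fc.values[i, j] - r) < 1e-12

    def test_constant_series_is_an_error_naming_the_region(self):
        with pytest.raises(ValueError, match="r1"):
            pearson_fc(ts([[1, 2, 3, 4], [2, 2, 2, 2]]))


class TestFisherFeatures:
    def test_zero_correlation_maps_to_zero(self):
        fc = FCMatrix(regions=["a", "b"], values=np.eye(2))
        out = fc_to_features(fc, T=50)
        assert out["fc__a__b"] == 0.0

    def test_closed_form_value(self):
        v = np.array([[1.0, 0.5], [0.5, 1.0]])
        out = fc_to_features(FCMatrix(regions=["a", "b"], values=v), T=103)
        assert out["fc__a__b"] == pytest.approx(np.arctanh(0.5) * 10, abs=1e-12)

    def test_full_atlas_feature_count(self):
        R = 103
        regions = schema.atlas_region_ids(R)
        out = fc_to_features(FCMatrix(regions=regions, values=np.eye(R)), T=150)
        assert len(out) == 5253  # R(R-1)/2

    @pytest.mark.parametrize("R", [2, 5, 17])
    def test_feature_count_formula(self, R):
        out = fc_to_features(FCMatrix(regions=[f"r{i}" for i in range(R)],
                                      values=np.eye(R)), T=20)
        assert len(out) == R * (R - 1) // 2

    def test_unit_correlation_stays_finite(self):
        v = np.array([[1.0, 1.0], [1.0, 1.0]])
        out = fc_to_features(FCMatrix(regions=["a", "b"], values=v), T=50)
        assert np.isfinite(out["fc__a__b"]) and out["fc__a__b"] > 40

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="T <= 3"):
            fc_to_features(FCMatrix(regions=["a", "b"], values=np.eye(2)), T=3)

    def test_permuting_regions_permutes_names_not_values(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((5, 60))
        a = fc_to_features(pearson_fc(ts(data)), T=60)
        perm = [3, 1, 4, 0, 2]
        b = fc_to_features(
            pearson_fc(ts(data[perm], regions=[f"r{i}" for i in perm])), T=60)
        assert sorted(np.round(a.to_numpy(), 12)) == sorted(np.round(b.to_numpy(), 12))

        def by_pair(series):
            return {frozenset(name.split("__")[1:]): v for name, v in series.items()}
        pa, pb = by_pair(a), by_pair(b)
        assert pa.keys() == pb.keys()
        for k in pa:
            assert pa[k] == pytest.approx(pb[k], abs=1e-12)


class TestRegionFilter:
    def make_subjects(self, n, missing=()):
        regions = schema.atlas_region_ids(110)
        rng = np.random.default_rng(1)
        out = []
        for k in range(n):
            keep = [r for r in regions if r not in missing or k % 2 == 0]
            out.append(TimeseriesSet(regions=keep,
                                     data=rng.standard_normal((len(keep), 8))))
        return out

    def test_no_missingness_keeps_full_atlas(self):
        mask = filter_regions(self.make_subjects(5))
        assert len(mask.retained) == 110 and not mask.removed

    def test_seven_dropped_regions_leave_103(self):
        missing = set(schema.atlas_region_ids(110)[:7])
        mask = filter_regions(self.make_subjects(10, missing), 0.1)
        assert len(mask.retained) == 103
        assert set(mask.removed) == missing

    def test_threshold_one_removes_nothing(self):
        missing = set(schema.atlas_region_ids(110)[:7])
        mask = filter_regions(self.make_subjects(10, missing), 1.0)
        assert len(mask.retained) == 110

    def test_threshold_validation(self):
        with pytest.raises(ValueError, match="threshold"):
            filter_regions(self.make_subjects(2), 0.0)

    def test_sporadically_missing_region_fills_null_features(self):
        regions = ["a", "b", "c"]
        rng = np.random.default_rng(2)
        full = TimeseriesSet(regions=regions, data=rng.standard_normal((3, 20)))
        partial = TimeseriesSet(regions=["a", "c"], data=rng.standard_normal((2, 20)))
        mask = filter_regions([full, partial], 0.6)  # b missing in 50% only
        assert mask.retained == regions
        v = features.subject_fc_features(partial, mask)
        assert v["fc__a__b"] == 0.0 and v["fc__b__c"] == 0.0
        assert v["fc__a__c"] != 0.0


class TestFreesurferStats:
    def synthetic_vector(self, seed=0):
        rng = np.random.default_rng(seed)
        names = schema.structural_feature_names()
        return pd.Series(rng.uniform(1, 100, len(names)).round(6), index=names)

    def test_writer_reader_round_trip(self, tmp_path):
        values = self.synthetic_vector()
        aseg, lh, rh = write_freesurfer_stats(values, tmp_path)
        back = read_freesurfer_stats(aseg, lh, rh)
        assert len(back) == 221
        pd.testing.assert_series_equal(back, values, atol=1e-6, check_exact=False)

    def test_missing_subcortical_row_is_reported_by_name(self, tmp_path):
        values = self.synthetic_vector()
        aseg, lh, rh = write_freesurfer_stats(values, tmp_path)
        lines = [l for l in aseg.read_text().splitlines()
                 if "Left-Hippocampus" not in l]
        aseg.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="Left-Hippocampus"):
            read_freesurfer_stats(aseg, lh, rh)

    def test_malformed_table_row_reports_line_number(self, tmp_path):
        values = self.synthetic_vector()
        aseg, lh, rh = write_freesurfer_stats(values, tmp_path)
        lines = aseg.read_text().splitlines()
        lines[10] = lines[10] + " extra_field"
        aseg.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match=":11:"):
            read_freesurfer_stats(aseg, lh, rh)


def test_unit_variance_of_scaled_features_under_null():
    # i.i.d. white-noise pairs, T=150: scaled Fisher features have SD ~ 1
    rng = np.random.default_rng(123)
    T, n_pairs = 150, 2000
    x = rng.standard_normal((n_pairs, T))
    y = rng.standard_normal((n_pairs, T))
    xc = x - x.mean(1, keepdims=True)
    yc = y - y.mean(1, keepdims=True)
    r = (xc * yc).sum(1) / np.sqrt((xc**2).sum(1) * (yc**2).sum(1))
    z = np.arctanh(r) * np.sqrt(T - 3)
    assert 0.95 < z.std(ddof=1) < 1.05


def test_cohort_table_counts_and_modalities(small_table):
    assert small_table.df.shape[1] == 221 + 12 * 11 // 2
    assert small_table.columns_of("structural") == schema.structural_feature_names()
    assert not small_table.df.isna().any().any()


def test_feature_table_round_trips_through_tsv(small_table, tmp_path):
    small_table.to_tsv(tmp_path / "t.tsv")
    back = features.FeatureTable.from_tsv(tmp_path / "t.tsv")
    pd.testing.assert_frame_equal(back.df, small_table.df.rename_axis("id"),
                                  atol=1e-9, check_exact=False)
    assert (back.modality == small_table.modality).all()
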