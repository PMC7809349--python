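"""Atlas building, ROI tables, paired tests, agreement and Z-score maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from oracles import signflip_pvalue

from mwimap.cohortstats import (bland_altman, build_atlas, format_roi_table,
                                paired_ttest, roi_metric_difference, roi_stats,
                                zscore_histogram, zscore_map)
from mwimap.core import QuantMap
from mwimap.reference import normative_table


class TestBuildAtlas:
    def test_identical_maps_give_zero_sd(self, rng):
        m = rng.uniform(0, 1, (4, 4, 2))
        atlas = build_atlas([m, m.copy(), m.copy()])
        assert np.allclose(atlas.sd_map.data, 0.0)
        assert np.allclose(atlas.mean_map.data, m)
        assert atlas.n_subjects == 3

    def test_hand_arithmetic(self):
        maps = [np.full((2, 2, 1), v) for v in (1.0, 2.0, 3.0)]
        atlas = build_atlas(maps)
        assert np.allclose(atlas.mean_map.data, 2.0)
        assert np.allclose(atlas.sd_map.data, 1.0)  # sample SD, n-1

    def test_nan_voxel_cropped_from_coverage(self):
        a = np.ones((2, 2, 1))
        b = np.ones((2, 2, 1))
        b[0, 0, 0] = np.nan
        atlas = build_atlas([a, b])
        assert not atlas.coverage_mask[0, 0, 0]
        assert np.isnan(atlas.mean_map.data[0, 0, 0])
        assert atlas.coverage_mask[1, 1, 0]

    def test_grid_mismatch_and_single_subject(self):
        with pytest.raises(ValueError):
            build_atlas([np.ones((2, 2, 1)), np.ones((3, 2, 1))])
        with pytest.raises(ValueError):
            build_atlas([np.ones((2, 2, 1))])


class TestRoiStats:
    def test_constant_map_has_zero_sd(self):
        labels = np.zeros((4, 4, 1), dtype=int)
        labels[:2] = 1
        labels[2:] = 2
        table = roi_stats(np.full((4, 4, 1), 0.25), labels)
        assert np.allclose(table["sd_pct"], 0.0)
        assert np.allclose(table["mean_pct"], 25.0)

    def test_voxel_counts_partition_the_mask(self, brain_truth):
        table = roi_stats(brain_truth.f_m_true, brain_truth.labels)
        assert table["n_voxels"].sum() == brain_truth.tissue_mask.sum()

    def test_formatting_one_decimal(self):
        labels = np.ones((2, 2, 1), dtype=int)
        table = format_roi_table(roi_stats(np.full((2, 2, 1), 0.12345), labels))
        assert table.loc["1", "mean_pct"] == 12.3


class TestRoiMetricDifference:
    def test_published_whole_cord_difference(self):
        mwf = normative_table("mwf")
        fm = normative_table("fm")
        assert roi_metric_difference(mwf, fm, "whole_cord") == pytest.approx(-3.4)

    def test_published_brain_difference(self):
        mwf = normative_table("mwf")
        fm = normative_table("fm")
        assert roi_metric_difference(mwf, fm, "all_wm_gm") == pytest.approx(6.2)

    def test_self_difference_zero_and_antisymmetry(self):
        mwf = normative_table("mwf")
        fm = normative_table("fm")
        assert roi_metric_difference(mwf, mwf, "genu") == 0.0
        assert roi_metric_difference(mwf, fm, "genu") == \
            -roi_metric_difference(fm, mwf, "genu")

    def test_missing_roi(self):
        mwf = normative_table("mwf")
        with pytest.raises(KeyError):
            roi_metric_difference(mwf, mwf, "no_such_roi")


class TestPairedTtest:
    def test_identical_samples(self):
        a = np.arange(5.0)
        t, p = paired_ttest(a, a)
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference(self):
        a = np.zeros(4)
        t, p = paired_ttest(a, a + 1.0)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_matches_signflip_oracle(self, rng):
        for _ in range(10):
            a = rng.normal(0, 1, 10)
            b = a + rng.normal(0.4, 1, 10)
            t, p = paired_ttest(a, b)
            p_exact = signflip_pvalue(a, b)
            assert abs(p - p_exact) <= 0.06

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_ttest([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_ttest([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_hand_arithmetic(self):
        r = bland_altman([1.0, 3.0], [2.0, 5.0])
        assert r.bias == pytest.approx(1.5)
        assert np.allclose(r.means, [1.5, 4.0])

    @given(c=st.floats(min_value=-5, max_value=5))
    @settings(deadline=None, max_examples=20)
    def test_constant_offset_collapses_limits(self, c):
        a = np.array([0.1, 0.5, 0.9, 1.3])
        r = bland_altman(a, a + c)
        assert r.bias == pytest.approx(c, abs=1e-12)
        assert r.loa_lo == pytest.approx(c, abs=1e-9)
        assert r.loa_hi == pytest.approx(c, abs=1e-9)

    def test_limits_bracket_most_differences(self, rng):
        a = rng.normal(0.2, 0.05, 200)
        b = a + rng.normal(0.03, 0.02, 200)
        r = bland_altman(a, b)
        inside = np.mean((r.diffs >= r.loa_lo) & (r.diffs <= r.loa_hi))
        assert 0.90 <= inside <= 1.0


class TestZScore:
    def _atlas(self, mean, sd, shape=(4, 4, 1)):
        m = np.full(shape, mean)
        s = np.full(shape, sd)
        return build_atlas([m - s, m + s])  # mean m, sd = s*sqrt(2)

    def test_subject_equal_to_mean_is_zero(self, rng):
        maps = [rng.uniform(0.1, 0.3, (4, 4, 1)) for _ in range(4)]
        atlas = build_atlas(maps)
        res = zscore_map(atlas.mean_map, atlas)
        assert np.allclose(res.z.data[np.isfinite(res.z.data)], 0.0)
        assert not res.deficient_mask.any()

    def test_cov_threshold_excludes_unreliable_voxels(self):
        mean = np.full((2, 2, 1), 1.0)
        sd = np.full((2, 2, 1), 0.5)
        sd[0, 0, 0] = 0.8  # CoV 0.8 > 0.75
        atlas = build_atlas([mean, mean])  # then override
        atlas.mean_map.data[:] = mean
        atlas.sd_map.data[:] = sd
        res = zscore_map(np.full((2, 2, 1), 1.0), atlas, cov_threshold=0.75)
        assert res.cov_excluded_mask[0, 0, 0]
        assert np.isnan(res.z.data[0, 0, 0])
        assert np.isfinite(res.z.data[1, 1, 0])

    def test_zero_sd_guard(self):
        m = np.full((2, 2, 1), 0.5)
        atlas = build_atlas([m, m.copy()])  # sd == 0 everywhere
        res = zscore_map(m + 0.1, atlas)
        assert res.cov_excluded_mask.all()
        assert np.all(np.isnan(res.z.data))

    def test_deficiency_cut(self):
        atlas = self._atlas(1.0, 0.1 / np.sqrt(2))
        subj = np.full((4, 4, 1), 1.0)
        subj[0, 0, 0] = 0.5  # z = -5
        res = zscore_map(subj, atlas, deficiency_cut=-1.96)
        assert res.deficient_mask[0, 0, 0]
        assert res.deficient_mask.sum() == 1

    def test_grid_mismatch(self):
        atlas = self._atlas(1.0, 0.1)
        with pytest.raises(ValueError):
            zscore_map(np.ones((3, 3, 1)), atlas)


class TestZscoreHistogram:
    def _map_of(self, values):
        z = QuantMap(np.array(values, dtype=float).reshape(-1, 1, 1), "z")
        from mwimap.cohortstats import ZScoreMap

        return ZScoreMap(z=z, deficient_mask=np.zeros(z.shape, bool),
                         cov_excluded_mask=np.zeros(z.shape, bool))

    def test_counts_conserve_defined_voxels(self):
        zm = self._map_of([-2.1, -0.3, 0.2, 0.25, 1.7, np.nan])
        edges, counts = zscore_histogram(zm, bin_width=0.5)
        assert counts.sum() == 5

    def test_empty_map(self):
        zm = self._map_of([np.nan, np.nan])
        edges, counts = zscore_histogram(zm)
        assert edges.size == 0 and counts.size == 0

    def test_shift_moves_support(self):
        zm1 = self._map_of([0.1, 0.4, 0.9])
        zm2 = self._map_of([2.1, 2.4, 2.9])
        e1, c1 = zscore_histogram(zm1, 0.5)
        e2, c2 = zscore_histogram(zm2, 0.5)
        assert np.allclose(e2, e1 + 2.0)
        assert np.array_equal(c1, c2)
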