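"""Sliding-window / static connectivity and variability analysis."""

import numpy as np
import pytest
from scipy import stats

from nirsdyn.connectivity import (
    edge_categories,
    group_srsfc_test,
    short_channel_variability,
    sliding_window_corr,
    static_rsfc,
    variability,
    variability_group_tests,
)
from nirsdyn.core import ChannelLayout, HemoSeries
from statsmodels.stats.multitest import multipletests

DT = 0.057


def _series(data, layout=None):
    return HemoSeries(hbo=np.asarray(data, float), dt_s=DT, layout=layout)


def naive_windowed_pearson(data, wl, step):
    """Brute-force per-window correlation oracle."""
    n_ch, n = data.shape
    starts = range(0, n - wl + 1, step)
    out = []
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            row = [np.corrcoef(data[i, s : s + wl], data[j, s : s + wl])[0, 1] for s in starts]
            out.append(row)
    return np.asarray(out)


class TestSlidingWindow:
    def test_matches_naive_oracle(self, rng):
        data = rng.standard_normal((3, 200))
        d = sliding_window_corr(_series(data), window_s=50 * DT, step_samples=1,
                                channels=np.arange(3))
        expected = naive_windowed_pearson(data, 50, 1)
        assert d.r.shape == expected.shape
        assert np.nanmax(np.abs(d.r - expected)) < 1e-12

    def test_self_copy_gives_unit_correlation(self, rng):
        x = rng.standard_normal(500)
        d = sliding_window_corr(_series(np.vstack([x, x])), channels=np.arange(2))
        assert np.allclose(d.r, 1.0)

    def test_36_channels_yield_630_edges(self, default_drsfc):
        assert default_drsfc.n_edges == 630

    def test_affine_rescaling_invariance(self, rng):
        data = rng.standard_normal((3, 300))
        scaled = data * np.array([[3.0], [-0.5], [10.0]]) + np.array([[1.0], [2.0], [-7.0]])
        d1 = sliding_window_corr(_series(data), window_s=60 * DT, channels=np.arange(3))
        d2 = sliding_window_corr(_series(scaled), window_s=60 * DT, channels=np.arange(3))
        # sign flips where the scale is negative
        signs = np.array([3.0, -0.5, 10.0])
        iu = d1.edges
        flip = np.sign(signs[iu[:, 0]] * signs[iu[:, 1]])
        assert np.nanmax(np.abs(d1.r * flip[:, None] - d2.r)) < 1e-12

    def test_zero_variance_window_marked_nan(self):
        data = np.vstack([np.r_[np.zeros(60), np.sin(np.arange(100))],
                          np.random.default_rng(0).standard_normal(160)])
        d = sliding_window_corr(_series(data), window_s=40 * DT, channels=np.arange(2))
        assert np.isnan(d.r[0, 0])
        assert np.isfinite(d.r[0, -1])

    def test_window_shorter_than_three_samples_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_corr(_series(np.zeros((2, 100))), window_s=DT,
                                channels=np.arange(2))


class TestStaticRSFC:
    def test_equals_full_length_window(self, rng):
        data = rng.standard_normal((4, 240))
        s = static_rsfc(_series(data), channels=np.arange(4))
        d = sliding_window_corr(_series(data), window_s=240 * DT, channels=np.arange(4))
        iu = d.edges
        assert np.allclose(s.r[iu[:, 0], iu[:, 1]], d.r[:, 0], atol=1e-12)

    def test_group_test_matches_bh_oracle(self):
        pvals = np.array([0.001, 0.01, 0.02, 0.05, 0.2])
        reject, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        # independent step-up oracle
        order = np.argsort(pvals)
        m = len(pvals)
        thresh = 0.05 * (np.arange(1, m + 1)) / m
        passed = np.flatnonzero(pvals[order] <= thresh)
        expect = np.zeros(m, bool)
        if passed.size:
            expect[order[: passed.max() + 1]] = True
        assert np.array_equal(reject, expect)

    def test_null_data_rarely_significant(self, rng):
        """20 subjects of pure noise: FDR-significant fraction stays ~0."""
        frac = []
        for _ in range(25):
            mats = [static_rsfc(_series(rng.standard_normal((6, 300))),
                                channels=np.arange(6)) for _ in range(20)]
            g = group_srsfc_test(mats, alpha=0.01)
            iu = np.triu_indices(6, 1)
            frac.append(g.fdr_mask[iu].mean())
        assert np.mean(frac) <= 0.02


def _roi_layout():
    rois = ["F", "F", "C", "C", "P", "P", "T", "T", "O", "O"]
    return ChannelLayout(
        channel_ids=tuple(f"C{i}" for i in range(10)),
        is_short=np.zeros(10, bool),
        roi=tuple(rois),
    )


class TestVariability:
    def test_constant_drsfc_has_zero_variance(self):
        layout = _roi_layout()
        x = np.tile(np.sin(np.arange(800) * 0.3), (10, 1))
        x += np.arange(10)[:, None]  # distinct offsets, identical dynamics
        d = sliding_window_corr(_series(x, layout), window_s=100 * DT, channels="standard")
        rep = variability(d, layout)
        assert np.nanmax(rep.edge_var) < 1e-20

    def test_five_rois_give_fifteen_categories(self, default_drsfc, clean_hemo):
        rep = variability(default_drsfc, clean_hemo.layout)
        assert len(rep.category_mean) == 15
        within = [c for c in rep.category_mean if c[0] == c[-1]]
        assert len(within) == 5

    def test_category_labels_sorted_pairs(self, default_drsfc, clean_hemo):
        cats = edge_categories(default_drsfc, clean_hemo.layout)
        assert all(c.split("-")[0] <= c.split("-")[1] for c in cats)

    def test_planted_structure_orders_variability(self):
        """Stable within-ROI coupling vs modulated between-ROI coupling:
        group t-test across synthetic subjects separates the two."""
        from nirsdyn.evaluation import variability_experiment

        res = variability_experiment(seed=40, n_subjects=8)
        assert res["mean_within"] < res["mean_between"]
        assert res["mean_short"] < res["mean_within"]
        assert res["tests"]["within_vs_between"]["p"] < 1e-3

    def test_group_tests_bonferroni_scaling(self, rng):
        a = rng.standard_normal(10)
        b = rng.standard_normal(10) + 5
        c = rng.standard_normal(10) - 5
        res = variability_group_tests(a, b, c)
        for key in ("within_vs_between", "within_vs_short", "between_vs_short"):
            assert res[key]["p_bonferroni"] == pytest.approx(
                min(1.0, res[key]["p"] * 3)
            )

    def test_type_I_error_calibrated(self):
        from nirsdyn.evaluation import variability_test_type_I

        rate = variability_test_type_I(seed=17, n_resamples=2000)
        assert 0.03 <= rate <= 0.07


def test_short_channel_variability_is_small(clean_hemo):
    sv = short_channel_variability(clean_hemo, step_samples=10)
    assert sv < 0.01
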