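"""Sliding-window correlation features and their bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfdfc import CohortSpec, generate_cohort, make_scheme
from mfdfc.dfc import (
    SlidingWindowConfig,
    build_dfc_features,
    count_segments,
    counts_to_tsv,
    dfc_feature_id,
    mixed_window_features,
    pairwise_discriminative_counts,
    sliding_window_corr,
)


def pearson_oracle(x, y, width, step):
    """Brute-force per-window Pearson correlation, np.corrcoef per window."""
    out = []
    t = 0
    while t + width <= len(x):
        out.append(np.corrcoef(x[t : t + width], y[t : t + width])[0, 1])
        t += step
    return np.array(out)


class TestCountSegments:
    @pytest.mark.parametrize("width,expected", [(15, 26), (20, 25), (25, 24), (30, 23)])
    def test_full_length_series(self, width, expected):
        assert count_segments(142, SlidingWindowConfig(width, 5)) == expected

    def test_single_full_window(self):
        assert count_segments(10, SlidingWindowConfig(10, 5)) == 1

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            count_segments(10, SlidingWindowConfig(11, 5))


class TestSlidingWindowCorr:
    def test_identical_series_give_unit_correlation(self, rng):
        x = rng.normal(size=142)
        out = sliding_window_corr(x, x, SlidingWindowConfig(15, 5))
        np.testing.assert_allclose(out, 1.0, atol=1e-12)

    def test_full_width_window_equals_global_pearson(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        out = sliding_window_corr(x, y, SlidingWindowConfig(60, 5))
        assert out.shape == (1,)
        assert out[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_matches_oracle_on_many_random_instances(self):
        for seed in range(100):
            r = np.random.default_rng(seed)
            x = r.normal(size=142)
            y = r.normal(size=142)
            got = sliding_window_corr(x, y, SlidingWindowConfig(15, 5))
            np.testing.assert_allclose(got, pearson_oracle(x, y, 15, 5), atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        width=st.integers(5, 40),
        step=st.integers(1, 10),
    )
    def test_oracle_equivalence_and_bounds_property(self, seed, width, step):
        r = np.random.default_rng(seed)
        x = r.normal(size=80)
        y = r.normal(size=80)
        cfg = SlidingWindowConfig(width, step)
        got = sliding_window_corr(x, y, cfg)
        assert got.size == count_segments(80, cfg)
        np.testing.assert_allclose(got, pearson_oracle(x, y, width, step), atol=1e-12)
        assert np.all(np.abs(got) <= 1 + 1e-12)
        np.testing.assert_allclose(
            got, sliding_window_corr(y, x, cfg), atol=1e-12
        )  # symmetry

    def test_zero_variance_window_recorded_as_zero(self, caplog):
        x = np.concatenate([np.zeros(20), np.random.default_rng(0).normal(size=20)])
        y = np.random.default_rng(1).normal(size=40)
        out = sliding_window_corr(x, y, SlidingWindowConfig(10, 10))
        assert out[0] == 0.0


class TestBuildFeatures:
    def test_paper_scale_column_counts(self):
        """10 + 5 selected ROIs at each window width give the expected totals."""
        series = np.random.default_rng(0).normal(size=(4, 20, 142))
        sel = {"Slow-5": list(range(5)), "Slow-4": list(range(5, 15))}
        scheme = make_scheme("Combined")
        expected = {15: 26 * 55, 20: 25 * 55, 25: 24 * 55, 30: 23 * 55}
        for w, cols in expected.items():
            dm = build_dfc_features(series, sel, scheme, SlidingWindowConfig(w, 5))
            assert dm.values.shape == (4, cols)

    def test_minimal_case_single_feature(self):
        series = np.random.default_rng(1).normal(size=(3, 2, 40))
        dm = build_dfc_features(
            series,
            {"Slow-4": [0, 1]},
            make_scheme("Slow-4"),
            SlidingWindowConfig(40, 5),
        )
        assert dm.values.shape == (3, 1)

    def test_values_bounded(self, small_cohort, combined_scheme):
        dm = build_dfc_features(
            small_cohort,
            {"Slow-5": [0, 1], "Slow-4": [2, 3]},
            combined_scheme,
            SlidingWindowConfig(15, 5),
        )
        assert np.all(np.abs(dm.values) <= 1 + 1e-12)

    def test_index_map_covers_every_column_once(self, small_cohort, combined_scheme):
        dm = build_dfc_features(
            small_cohort,
            {"Slow-5": [0, 1, 4], "Slow-4": [2, 3]},
            combined_scheme,
            SlidingWindowConfig(20, 5),
        )
        assert len(dm.index_map) == dm.n_features
        assert len(set(dm.index_map)) == dm.n_features
        assert len(set(dm.feature_ids)) == dm.n_features

    def test_conventional_scheme_filters_blocks_with_single_band(self, small_cohort):
        scheme = make_scheme("Conventional")
        dm = build_dfc_features(
            small_cohort,
            {"Slow-5": [0, 1], "Slow-4": [2, 3]},
            scheme,
            SlidingWindowConfig(15, 5),
        )
        # two blocks survive, each 1 pair x 26 segments
        assert dm.values.shape == (16, 52)

    def test_out_of_range_roi_rejected(self, small_cohort, combined_scheme):
        with pytest.raises(ValueError, match="out of range"):
            build_dfc_features(
                small_cohort,
                {"Slow-4": [0, 99]},
                combined_scheme,
                SlidingWindowConfig(15, 5),
            )

    def test_all_blocks_below_pair_size_rejected(self, small_cohort, combined_scheme):
        with pytest.raises(ValueError, match="pairs"):
            build_dfc_features(
                small_cohort,
                {"Slow-4": [0]},
                combined_scheme,
                SlidingWindowConfig(15, 5),
            )


class TestMixedWindows:
    def test_distinct_widths_concatenate_blockwise(self):
        series = np.random.default_rng(2).normal(size=(3, 50, 142))
        sel = {"Slow-5": list(range(5)), "Slow-4": list(range(5, 15))}
        dm = mixed_window_features(
            series,
            sel,
            make_scheme("Combined"),
            {"Slow-5": SlidingWindowConfig(15, 5), "Slow-4": SlidingWindowConfig(20, 5)},
        )
        assert dm.values.shape[1] == 26 * 10 + 25 * 45  # 260 + 1125

    def test_equal_configs_reduce_to_single_width(self, small_cohort, combined_scheme):
        sel = {"Slow-5": [0, 1], "Slow-4": [2, 3, 4]}
        cfg = SlidingWindowConfig(15, 5)
        a = build_dfc_features(small_cohort, sel, combined_scheme, cfg)
        b = mixed_window_features(
            small_cohort, sel, combined_scheme, {"Slow-5": cfg, "Slow-4": cfg}
        )
        np.testing.assert_allclose(a.values, b.values)
        assert a.index_map == b.index_map

    def test_missing_band_config_rejected(self, small_cohort, combined_scheme):
        with pytest.raises(ValueError, match="config"):
            mixed_window_features(
                small_cohort,
                {"Slow-5": [0, 1], "Slow-4": [2, 3]},
                combined_scheme,
                {"Slow-5": SlidingWindowConfig(15, 5)},
            )


class TestPairCounts:
    def test_empty_selection_gives_empty_counts(self):
        assert pairwise_discriminative_counts([], []) == {}

    def test_counts_partition_selected_features(self):
        index_map = [
            (s, a, b, "Slow-4") for s in range(3) for (a, b) in [(0, 1), (0, 2), (1, 2)]
        ]
        counts = pairwise_discriminative_counts([0, 1, 3, 6, 8], index_map)
        assert sum(counts.values()) == 5
        assert counts[(0, 1, "Slow-4")] == 3  # segments 0, 1, 2

    def test_tsv_serialisation(self):
        counts = {(0, 1, "Slow-4"): 3, (2, 4, "Slow-5"): 1}
        text = counts_to_tsv(counts)
        assert "Slow-4\tROI1\tROI2\t3" in text


def test_injected_pair_effect_maximises_group_swc_difference():
    """The pair with a group-specific correlation shows the largest mean gap."""
    spec = CohortSpec(
        n_per_group=10,
        n_rois=6,
        noise_sd=0.2,
        seed=17,
        dfc_effects=((1, 4, "Slow-4", 0.8, 0.0),),
    )
    cohort = generate_cohort(spec)
    dm = build_dfc_features(
        cohort,
        {"Slow-4": [0, 1, 2, 3, 4, 5]},
        make_scheme("Slow-4"),
        SlidingWindowConfig(20, 5),
    )
    diff = np.abs(
        dm.values[cohort.labels == 1].mean(0) - dm.values[cohort.labels == 0].mean(0)
    )
    per_pair: dict = {}
    for col, (_s, a, b, _band) in enumerate(dm.index_map):
        per_pair.setdefault((a, b), []).append(diff[col])
    means = {k: np.mean(v) for k, v in per_pair.items()}
    assert max(means, key=means.get) == (1, 4)


def test_feature_id_format():
    assert dfc_feature_id("Slow-4", 3, 0, 5) == "Slow-4:seg3:ROI1-ROI6"
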