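"""Dose-response statistics: normalization, Dunnett testing, star labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nanohcs import dose_stats


class TestStarLabel:
    @pytest.mark.parametrize(
        "p, label",
        [
            (0.03, "*"),
            (0.0005, "***"),
            (0.05, "ns"),  # strict inequality at the boundary
            (0.009, "**"),
            (5e-5, "****"),
            (0.2, "ns"),
            (0.01, "*"),
            (0.001, "**"),
            (0.0001, "***"),
        ],
    )
    def test_printed_thresholds(self, p, label):
        assert dose_stats.star_label(p) == label

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dose_stats.star_label(1.5)

    @given(st.floats(min_value=0, max_value=1, allow_nan=False))
    @settings(max_examples=50, derandomize=True)
    def test_label_consistent_with_bins(self, p):
        label = dose_stats.star_label(p)
        if label == "ns":
            assert p >= 0.05
        else:
            assert p < (0.05, 0.01, 0.001, 0.0001)[len(label) - 1]


class TestNormalize:
    def test_control_is_identity_100pct(self):
        rel = dose_stats.normalize_to_control({0.0: 5.0, 10.0: 10.0})
        assert rel[0.0] == 100.0
        assert rel[10.0] == 200.0

    def test_zero_control_raises_with_metric_name(self):
        with pytest.raises(ValueError, match="ros"):
            dose_stats.normalize_to_control({0.0: 0.0, 10.0: 1.0}, metric="ros")

    def test_scale_invariance(self):
        means = {0.0: 3.0, 5.0: 4.5, 10.0: 6.0}
        rel1 = dose_stats.normalize_to_control(means)
        rel2 = dose_stats.normalize_to_control({k: 7.3 * v for k, v in means.items()})
        pd.testing.assert_series_equal(rel1, rel2)


class TestAnovaDunnett:
    def test_identical_groups_give_p_near_one(self):
        vals = np.array([1.0, 1.1, 0.9, 1.05])
        res = dose_stats.anova_dunnett({0.0: vals, 10.0: vals.copy()})
        assert res.p_adjusted[0] > 0.99

    def test_adjusted_p_at_least_unadjusted(self):
        rng = np.random.default_rng(1)
        groups = {float(d): rng.normal(d / 50.0, 1.0, 4) for d in (0, 10, 50, 100)}
        res = dose_stats.anova_dunnett(groups)
        assert (res.p_adjusted >= res.p_unadjusted - 1e-12).all()

    def test_matches_monte_carlo_oracle(self):
        # small toy data; oracle = simulated null distribution of the
        # many-to-one max-|t| statistic with pooled variance
        control = np.array([1.0, 1.2, 0.9, 1.1])
        g1 = np.array([1.3, 1.5, 1.2, 1.4])
        g2 = np.array([1.0, 1.1, 0.9, 1.2])
        res = dose_stats.anova_dunnett({0.0: control, 1.0: g1, 2.0: g2})

        rng = np.random.default_rng(12345)
        n_sim, n, k = 400_000, 4, 3
        data = rng.standard_normal((n_sim, k, n))
        means = data.mean(axis=2)
        ss = ((data - means[:, :, None]) ** 2).sum(axis=(1, 2))
        df = k * n - k
        s = np.sqrt(ss / df)
        t = (means[:, 1:] - means[:, :1]) / (s[:, None] * np.sqrt(2.0 / n))
        max_abs_t = np.abs(t).max(axis=1)
        for i in range(2):
            p_mc = (max_abs_t >= abs(res.statistics[i])).mean()
            assert res.p_adjusted[i] == pytest.approx(p_mc, abs=0.005)

    def test_familywise_type1_error_calibrated(self):
        # 1000 simulated null plates (4 doses x 3 field means): the rate of
        # any Dunnett rejection at alpha=0.05 must sit in [0.03, 0.07]
        rng = np.random.default_rng(7)
        rejections = 0
        n_plates = 1000
        for _ in range(n_plates):
            groups = {float(d): rng.normal(0.0, 1.0, 3) for d in (0, 1, 2, 3)}
            res = dose_stats.anova_dunnett(groups)
            rejections += bool((res.p_adjusted < 0.05).any())
        assert 0.03 <= rejections / n_plates <= 0.07

    def test_rejects_degenerate_groups(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            dose_stats.anova_dunnett({0.0: [1.0], 10.0: [1.0, 2.0]})
        with pytest.raises(ValueError, match="control"):
            dose_stats.anova_dunnett({10.0: [1.0, 2.0], 20.0: [2.0, 3.0]},
                                     control_dose=0.0)


class TestSummarize:
    @staticmethod
    def _toy_cells(rng, ros_by_dose):
        rows = []
        for dose, ros_mu in ros_by_dose.items():
            for f in range(3):
                for _ in range(40):
                    rows.append(dict(
                        dose=dose, field_id=f"d{dose}f{f}",
                        ros_mean=rng.normal(ros_mu, 5.0),
                        mito_mean_intensity=rng.normal(2000, 100),
                        mito_count=rng.poisson(6),
                        cell_area_um2=rng.normal(500, 50),
                        form_factor=rng.uniform(0.4, 0.8),
                        is_dead=rng.random() < 0.05,
                    ))
        return pd.DataFrame(rows)

    def test_control_row_is_exactly_100pct(self):
        cells = self._toy_cells(np.random.default_rng(2),
                                {0.0: 100.0, 50.0: 150.0})
        summary, report = dose_stats.summarize_conditions(cells)
        assert (summary[summary.dose == 0.0].relative_pct.dropna() == 100.0).all()
        assert (summary[summary.dose == 0.0].stars == "").all()

    def test_relative_metrics_scale_invariant(self):
        rng = np.random.default_rng(3)
        cells = self._toy_cells(rng, {0.0: 100.0, 50.0: 130.0})
        scaled = cells.copy()
        for col in ("ros_mean", "mito_mean_intensity"):
            scaled[col] *= 11.0
        s1, _ = dose_stats.summarize_conditions(cells)
        s2, _ = dose_stats.summarize_conditions(scaled)
        pd.testing.assert_series_equal(s1.relative_pct, s2.relative_pct)

    def test_star_labels_consistent_with_p(self):
        cells = self._toy_cells(np.random.default_rng(4),
                                {0.0: 100.0, 50.0: 160.0, 100.0: 100.0})
        summary, _ = dose_stats.summarize_conditions(cells)
        tested = summary[summary.p_value.notna()]
        for _, row in tested.iterrows():
            assert row.stars == dose_stats.star_label(row.p_value)

    def test_monotone_area_effect_recovered(self, recovery_cells):
        # generator shrinks cell area only at the top dose; mean relative
        # areas must be ordered accordingly
        summary, _ = dose_stats.summarize_conditions(recovery_cells)
        area = summary[summary.metric == "area"].set_index("dose").relative_pct
        assert area[0.0] == 100.0
        assert abs(area[50.0] - 100.0) < 5.0
        assert area[100.0] < 90.0
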