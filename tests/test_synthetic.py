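"""Generator contracts: determinism, truth/image consistency, intensity
margins, assay tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nanohcs.images import read_field
from nanohcs.linfit import LinearFit
from nanohcs.synthetic import (
    EffectConfig,
    generate_absorbance_table,
    generate_dose_series,
    generate_field,
    generate_relaxation_table,
    truth_cell_mask,
    truth_nucleus_mask,
)


def small_config(**over):
    base = dict(doses=[0.0, 50.0], cells_per_field=40, field_shape=(512, 512),
                min_cells_per_dose=80, seed=3)
    base.update(over)
    return EffectConfig(**base)


class TestGenerateField:
    def test_fixed_seed_is_bit_identical(self):
        cfg = small_config()
        img1, truth1 = generate_field(cfg, 0.0, 99)
        img2, truth2 = generate_field(cfg, 0.0, 99)
        for role in img1.channels:
            assert np.array_equal(img1[role], img2[role])
        pd.testing.assert_frame_equal(truth1, truth2)

    def test_no_dead_no_noise_gives_flat_dead_channel(self):
        cfg = small_config(dead_fraction=0.0, noise_sd=0.0)
        img, truth = generate_field(cfg, 0.0, 1)
        assert np.all(img["dead"] == cfg.background_level)
        assert not truth.is_dead.any()

    def test_dead_count_within_binomial_99_interval(self):
        # 500 cells at dead_fraction 0.3: realized draw must sit inside the
        # central 99% of Binomial(n, 0.3)
        cfg = small_config(cells_per_field=100, field_shape=(1024, 1024),
                           dead_fraction=0.3)
        n_total, n_dead = 0, 0
        for fs in range(5):
            _, truth = generate_field(cfg, 0.0, fs)
            n_total += len(truth)
            n_dead += int(truth.is_dead.sum())
        assert n_total == 500
        lo = stats.binom.ppf(0.005, n_total, 0.3)
        hi = stats.binom.ppf(0.995, n_total, 0.3)
        assert lo <= n_dead <= hi

    def test_masks_do_not_overlap_and_stay_in_bounds(self):
        cfg = small_config()
        img, truth = generate_field(cfg, 50.0, 11)
        occupied = np.zeros(cfg.field_shape, dtype=int)
        for _, row in truth.iterrows():
            occupied += truth_cell_mask(row, cfg.field_shape)
        assert occupied.max() == 1  # pairwise disjoint
        assert int(occupied.sum()) == int(truth.area_px.sum())

    def test_truth_masks_reproduce_cyto_foreground(self):
        cfg = small_config(noise_sd=0.0)
        img, truth = generate_field(cfg, 0.0, 7)
        union = np.zeros(cfg.field_shape, dtype=bool)
        for _, row in truth.iterrows():
            union |= truth_cell_mask(row, cfg.field_shape)
        assert np.array_equal(img["cyto_ros"] > cfg.background_level, union)

    def test_dead_live_nuclear_intensity_margins(self):
        # dead nuclei >= 3.5x background, live <= 1.5x: a margin around the
        # 3x classification rule
        cfg = small_config(dead_fraction=0.5)
        img, truth = generate_field(cfg, 0.0, 5)
        dead_ch = img["dead"].astype(float)
        for _, row in truth.iterrows():
            mask = truth_nucleus_mask(row, cfg.field_shape)
            ratio = dead_ch[mask].mean() / cfg.background_level
            if row.is_dead:
                assert ratio >= 3.5
            else:
                assert ratio <= 1.5

    def test_border_cell_present_when_enough_cells(self):
        cfg = small_config(cells_per_field=25)
        _, truth = generate_field(cfg, 0.0, 2)
        assert truth.touches_border.sum() >= 1

    def test_rejects_unknown_dose_and_small_field(self):
        cfg = small_config()
        with pytest.raises(ValueError, match="not in config.doses"):
            generate_field(cfg, 33.0, 1)
        with pytest.raises(ValueError, match="256"):
            generate_field(small_config(field_shape=(128, 128)), 0.0, 1)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="control"):
            EffectConfig(doses=[10.0])
        with pytest.raises(ValueError, match="dead_fraction"):
            EffectConfig(doses=[0.0], dead_fraction=1.4)
        with pytest.raises(ValueError, match="axis_ratio"):
            EffectConfig(doses=[0.0], axis_ratio=0.0)


class TestDoseSeries:
    def test_bookkeeping_and_roundtrip(self, tmp_path):
        cfg = EffectConfig(doses=[0.0, 10.0, 50.0], cells_per_field=30,
                           field_shape=(384, 384), min_cells_per_dose=60, seed=4)
        plate = generate_dose_series(cfg, fields_per_dose=2)
        assert len(plate.fields) == 6
        assert len(plate.layout) == 6
        paths = plate.write(tmp_path)
        assert len(list(paths["images"].glob("*.tif"))) == 24  # 4 channels/field
        for fimg in plate.fields:  # lossless TIFF round-trip
            back = read_field(paths["images"], fimg.field_id)
            for role in fimg.channels:
                assert np.array_equal(back[role], fimg[role])

    def test_extends_fields_to_reach_min_cells(self):
        cfg = EffectConfig(doses=[0.0], cells_per_field=30, field_shape=(512, 512),
                           min_cells_per_dose=90, seed=1)
        with pytest.warns(UserWarning, match="extending"):
            plate = generate_dose_series(cfg, fields_per_dose=1)
        assert plate.layout.n_cells.sum() >= 90

    def test_control_axis_ratio_moment(self):
        cfg = EffectConfig(doses=[0.0], cells_per_field=60, field_shape=(768, 768),
                           min_cells_per_dose=120, axis_ratio=0.6, seed=8)
        plate = generate_dose_series(cfg, fields_per_dose=2)
        ratios = plate.truth.axis_ratio
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 0.6) <= 3 * se + 1e-3


class TestAssayTables:
    def test_absorbance_noiseless_inversion(self):
        table = generate_absorbance_table(0.008, 0.02, [0, 20, 40, 60, 80, 100])
        fit = LinearFit.fit(table.concentration_ug_ml, table.absorbance)
        assert fit.slope == pytest.approx(0.008, abs=1e-12)
        assert fit.intercept == pytest.approx(0.02, abs=1e-12)
        assert table.absorbance.iloc[0] == pytest.approx(0.02)

    def test_absorbance_exceeds_linear_range_at_high_conc(self):
        table = generate_absorbance_table(0.01, 0.05, [100.0])
        assert table.absorbance.iloc[0] == pytest.approx(1.05)

    def test_absorbance_rejects_negative_noise(self):
        with pytest.raises(ValueError):
            generate_absorbance_table(0.01, 0.0, [0, 10], noise_sd=-1)

    def test_relaxation_zero_relaxivity_flat(self):
        table = generate_relaxation_table(0.0, 0.4, [0, 1, 2, 3])
        assert np.allclose(table.T_s, 1 / 0.4)

    def test_relaxation_rates_stay_positive_under_noise(self):
        table = generate_relaxation_table(1.0, 0.1, [0, 0.5, 1], noise_sd=0.05,
                                          seed=2)
        assert (table.T_s > 0).all()

    def test_relaxation_rejects_bad_config(self):
        with pytest.raises(ValueError):
            generate_relaxation_table(1.0, 0.0, [0, 1])
        with pytest.raises(ValueError):
            generate_relaxation_table(-1.0, 0.4, [0, 1])
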