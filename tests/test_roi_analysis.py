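"""Expanding-ROI series, MTR, variants table, robustness curves."""

import numpy as np
import pandas as pd
import pytest

from utemt import PhantomSpec, make_phantom
from utemt.roi_analysis import (
    DEFAULT_FF_TARGETS,
    build_roi_series,
    compute_mtr,
    robustness_curves,
    run_variants,
)
from utemt.synthetic_data import LABEL_FAT, LABEL_MUSCLE


@pytest.fixture(scope="module")
def labels():
    return make_phantom(PhantomSpec()).labels


class TestROISeries:
    def test_ff_zero_has_no_fat(self, labels):
        series = build_roi_series(labels, n_series=2)
        for s in series:
            assert np.sum(labels[s.masks[0]] == LABEL_FAT) == 0

    def test_ff_count_identity(self, labels):
        """FF = 50% on an 8x8 = 64-voxel muscle seed means exactly 64 fat
        voxels (fat count equals muscle count)."""
        series = build_roi_series(labels, n_series=1, ff_targets=(0.0, 50.0))
        s = series[0]
        m = s.masks[-1]
        n_fat = int(np.sum(labels[m] == LABEL_FAT))
        n_mus = int(np.sum(labels[m] == LABEL_MUSCLE))
        assert n_fat == n_mus == 64
        assert s.ff_percent[-1] == pytest.approx(50.0)

    def test_muscle_voxels_kept_intact(self, labels):
        """The seed muscle voxel set is identical across every mask of a
        series; masks are nested; FF achieved within half a voxel of the
        closest achievable value."""
        series = build_roi_series(labels)
        for s in series:
            seed_set = set(map(tuple, np.argwhere(s.seed_mask)))
            n_mus = len(seed_set)
            for mask, ff, tgt in zip(s.masks, s.ff_percent, s.ff_target):
                mus_in_mask = set(
                    map(tuple, np.argwhere(mask & (labels == LABEL_MUSCLE)))
                )
                assert mus_in_mask == seed_set
                half_voxel_ff = 100.0 * 1 / (n_mus + 1) / 2 + 1e-9
                assert abs(ff - tgt) <= max(half_voxel_ff, 100.0 / (n_mus + 1))

    def test_unreachable_target_raises(self):
        labels_small = make_phantom(
            PhantomSpec(shape=(24, 24), background_width=2, muscle_fraction=0.8)
        ).labels
        with pytest.raises(ValueError, match="unreachable"):
            build_roi_series(
                labels_small, n_series=1, ff_targets=(0.0, 70.0), seed_size=8
            )

    def test_determinism(self, labels):
        a = build_roi_series(labels, n_series=3)
        b = build_roi_series(labels, n_series=3)
        for sa, sb in zip(a, b):
            for ma, mb in zip(sa.masks, sb.masks):
                assert np.array_equal(ma, mb)


class TestMTR:
    def test_limits(self):
        grid = np.ones((3, 5))
        grid[1, 0] = 1.0
        assert compute_mtr(grid, 1.0) == 0.0
        grid[1, 0] = 0.0
        assert compute_mtr(grid, 1.0) == 100.0

    def test_missing_operating_point(self):
        with pytest.raises(ValueError, match="not in the protocol"):
            compute_mtr(np.ones((3, 5)), 1.0, offset_khz=3.0)

    def test_pure_fat_nearly_inert(self, default_study):
        """Noise-free pure-fat ROI has MTR < 5%."""
        mask = default_study.phantom.fat_mask
        mt = default_study.mt[:, :, mask].mean(axis=2)
        ref = float(default_study.mt_ref[mask].mean())
        assert compute_mtr(mt, ref) < 5.0


class TestRunVariants:
    def test_baseline_recovery(self, roi_table):
        """FF = 0 rows: variant-4 MMF within 0.1 points of the ground-truth
        muscle MMF (9%), T1 within 0.1% of 972 ms (noise-free end-to-end)."""
        base = roi_table[roi_table.ff_target == 0.0]
        assert len(base) == 7
        assert np.allclose(base.mmf_v4, 9.0, atol=0.1)
        assert np.allclose(base.t1_ms, 972.0, rtol=1e-3)
        assert base.b1_valid.all()

    def test_variant_1_equals_2_under_uniform_unit_b1(self, uniform_b1_study):
        """With a uniform B1 = 1 field the B1 correction is a no-op and the
        two constant-T1 variants coincide."""
        series = build_roi_series(
            uniform_b1_study.phantom.labels, n_series=2,
            ff_targets=(0.0, 20.0, 50.0),
        )
        t = run_variants(series, uniform_b1_study)
        assert np.allclose(t.mmf_v1, t.mmf_v2, atol=1e-3)
        assert np.allclose(t.mmf_v3, t.mmf_v4, atol=1e-3)

    def test_measured_t1_below_constant_at_high_ff(self, roi_table):
        """At FF = 35% the measured (apparent) T1 sits strictly below the
        750 ms constant, mirroring the mixed-ROI T1 compression."""
        rows = roi_table[roi_table.ff_target == 35.0]
        assert (rows.t1_ms < 750.0).all()
        assert (rows.t1_ms > 233.0).all()

    def test_no_rows_dropped(self, roi_table):
        assert len(roi_table) == 7 * len(DEFAULT_FF_TARGETS)


class TestRobustnessCurves:
    def test_normalization_identity(self, roi_table):
        """Every curve passes through (FF=0, 100) exactly."""
        for c in robustness_curves(roi_table):
            assert c.normalized_mean[0] == pytest.approx(100.0, abs=1e-12)
            assert (c.per_series_normalized[0.0] == 100.0).all()

    def test_constant_metric_fully_robust(self, roi_table):
        t = roi_table.copy()
        t["mtr_percent"] = 42.0
        (c,) = robustness_curves(t, metrics=("mtr",))
        assert np.allclose(c.normalized_mean, 100.0)
        assert c.robustness_ff == max(c.ff)

    def test_missing_baseline_rejected(self, roi_table):
        with pytest.raises(ValueError, match="baseline"):
            robustness_curves(roi_table[roi_table.ff_target > 0.0])

    def test_mechanism_dilution_and_compensation(self, roi_table):
        """Fat dilutes the apparent MT effect: MTR and constant-T1 MMF
        decrease strictly with FF; feeding the (lower) measured T1 into the
        model compensates — its MMF deviates from baseline strictly less
        than the constant-T1 MMF at every FF > 0."""
        curves = {c.metric: c for c in robustness_curves(roi_table)}
        for m in ("mtr", "mmf_v1", "mmf_v2"):
            assert np.all(np.diff(curves[m].normalized_mean) < 0), m
        dev4 = np.abs(curves["mmf_v4"].normalized_mean - 100.0)[1:]
        dev2 = np.abs(curves["mmf_v2"].normalized_mean - 100.0)[1:]
        assert np.all(dev4 < dev2)
        assert curves["mmf_v4"].robustness_ff >= curves["mmf_v2"].robustness_ff

    def test_t1_robustness_range(self, roi_table):
        """Apparent T1 loses more than 5% of its baseline above FF = 10%."""
        (c,) = robustness_curves(roi_table, metrics=("t1",))
        assert c.robustness_ff <= 10.0
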