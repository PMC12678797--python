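"""ROI rasterization and the SNR/CNR/ReCon repeat-series metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwiphantom.roi import (
    DegenerateSeriesError,
    MetricResult,
    ROISampleSeries,
    ROISpec,
    cnr_mult,
    metric_table,
    metrics_to_frame,
    rasterize_roi,
    recon,
    recon_series,
    snr_mult,
    summary_to_frame,
    temporal_sd,
)
from dwiphantom.acquisition import simulate_series

from conftest import clean_protocol


def series_of(values):
    """ROISampleSeries from a (n_repeats, n_pixels) list."""
    arr = np.asarray(values, dtype=float)
    roi = ROISpec("x", (0.0, 0.0), 74.0)
    return ROISampleSeries(roi=roi, values=arr)


class TestRasterize:
    def test_74mm3_roi_pixel_count(self):
        # 74 mm³ / 3 mm slice = 24.67 mm² -> ~99 pixels at 0.5 mm (within 5%)
        roi = ROISpec("c", (0.0, 0.0), 74.0)
        rows, cols = rasterize_roi(roi, (101, 101), 0.5)
        assert abs(len(rows) - 24.67 / 0.25) / (24.67 / 0.25) < 0.05

    def test_4mm3_roi_pixel_count(self):
        roi = ROISpec("c", (0.0, 0.0), 4.0)
        rows, cols = rasterize_roi(roi, (101, 101), 0.5)
        assert 3 <= len(rows) <= 7  # ~5 pixels

    def test_center_outside_grid_rejected(self):
        roi = ROISpec("c", (100.0, 0.0), 74.0)
        with pytest.raises(ValueError, match="outside"):
            rasterize_roi(roi, (21, 21), 0.5)

    def test_subpixel_roi_rejected(self):
        roi = ROISpec("c", (0.26, 0.26), 0.05)
        with pytest.raises(ValueError, match="zero pixels"):
            rasterize_roi(roi, (21, 21), 0.5)


class TestTemporalSD:
    def test_identical_repeats_give_zero(self):
        assert temporal_sd(series_of([[5.0, 7.0], [5.0, 7.0]])) == 0.0

    def test_two_pixel_hand_example(self):
        # pixel A [10, 14], pixel B [20, 16]: per-pixel sample SDs 2.828 each
        s = series_of([[10.0, 20.0], [14.0, 16.0]])
        assert temporal_sd(s) == pytest.approx(2.8284271, abs=1e-6)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            temporal_sd(series_of([[1.0, 2.0]]))

    def test_recovers_gaussian_sigma(self):
        rng = np.random.default_rng(5)
        s = series_of(100.0 + rng.normal(0, 3.0, (10, 400)))
        assert temporal_sd(s) == pytest.approx(3.0, rel=0.15)


class TestSNR:
    def test_hand_example(self):
        # per-repeat means 15, 15; temporal SD 2.828 -> SNR 5.303
        s = series_of([[10.0, 20.0], [14.0, 16.0]])
        assert snr_mult(s) == pytest.approx(5.3033, abs=1e-3)

    def test_doubling_signal_at_fixed_noise_doubles_snr(self):
        s = series_of([[10.0, 20.0], [14.0, 16.0]])
        # double each pixel's mean, keep the temporal fluctuations: SNR doubles
        means = s.values.mean(axis=0, keepdims=True)
        doubled = series_of(2 * means + (s.values - means))
        assert snr_mult(doubled) == pytest.approx(2 * snr_mult(s))

    def test_invariant_when_signal_and_noise_scale_together(self):
        s = series_of([[10.0, 20.0], [14.0, 16.0]])
        s2 = series_of([[20.0, 40.0], [28.0, 32.0]])
        assert snr_mult(s2) == pytest.approx(snr_mult(s))

    def test_noiseless_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            snr_mult(series_of([[5.0, 7.0], [5.0, 7.0]]))

    def test_constant_offset_shifts_snr_by_k_over_sd(self):
        s = series_of([[10.0, 20.0], [14.0, 16.0]])
        shifted = series_of([[15.0, 25.0], [19.0, 21.0]])
        sd = temporal_sd(s)
        assert snr_mult(shifted) == pytest.approx(snr_mult(s) + 5.0 / sd)


class TestCNR:
    def test_hand_example(self):
        # lesion means 30, 32; background means 20, 24; SD_GM = 2.828
        lesion = series_of([[30.0], [32.0]])
        bg = [series_of([[18.0, 22.0], [22.0, 26.0]])]
        expected = ((30 - 20) + (32 - 24)) / 2 / 2.8284271
        assert cnr_mult(lesion, bg) == pytest.approx(expected, abs=1e-4)

    def test_lesion_equal_background_gives_zero(self):
        lesion = series_of([[20.0, 24.0], [22.0, 26.0]])
        assert cnr_mult(lesion, [lesion]) == pytest.approx(0.0)

    def test_constant_offset_leaves_cnr_unchanged(self):
        lesion = series_of([[30.0], [32.0]])
        bg = [series_of([[18.0, 22.0], [22.0, 26.0]])]
        lesion_k = series_of([[37.0], [39.0]])
        bg_k = [series_of([[25.0, 29.0], [29.0, 33.0]])]
        assert cnr_mult(lesion_k, bg_k) == pytest.approx(cnr_mult(lesion, bg))

    def test_pooled_identical_background_equals_single(self):
        lesion = series_of([[30.0], [32.0]])
        bg = series_of([[18.0, 22.0], [22.0, 26.0]])
        assert cnr_mult(lesion, [bg] * 4) == pytest.approx(cnr_mult(lesion, [bg]))


class TestReCon:
    def test_printed_10mm_pair_rounds_to_006(self):
        assert round(recon(676.31, 597.8), 2) == 0.06

    def test_symmetric_inputs_give_zero(self):
        assert recon(55.0, 55.0) == 0.0

    def test_hand_example(self):
        assert recon(110.0, 90.0) == pytest.approx(0.10)

    def test_printed_single_repeat_cnr_arithmetic(self):
        # (435.79 - 426.49) / 19.05 = 0.488: the CNR formula on printed values
        assert (435.79 - 426.49) / 19.05 == pytest.approx(0.488, abs=5e-4)

    @settings(deadline=None, max_examples=50)
    @given(a=st.floats(0.01, 1e4), b=st.floats(0.01, 1e4))
    def test_bounded_and_antisymmetric(self, a, b):
        r = recon(a, b)
        assert -1.0 <= r <= 1.0
        assert recon(b, a) == pytest.approx(-r, abs=1e-12)

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ValueError):
            recon(0.0, 0.0)

    def test_series_recon_is_recon_of_per_repeat_means(self):
        lesion = series_of([[30.0, 34.0], [36.0, 38.0]])
        bg = [series_of([[18.0, 22.0], [22.0, 26.0]])]
        per = recon_series(lesion, bg, per_repeat=True)
        assert per[0] == pytest.approx(recon(32.0, 20.0))
        assert per[1] == pytest.approx(recon(37.0, 24.0))


@pytest.fixture(scope="module")
def table(compact_grids):
    protocol = clean_protocol(
        n_repeats=3, noise_sigma=10.0, temperature_schedule=(20.0,) * 3
    )
    series = {
        sid: simulate_series(compact_grids, protocol, master_seed=i)
        for i, sid in enumerate(("A", "B", "C"))
    }
    return metric_table(series)


class TestMetricTable:
    def test_cardinality(self, table):
        # 3 sequences x 5 lesion sizes x 5 metrics lesion-level rows + aggregates
        lesion_rows = [r for r in table if r.lesion_label != "all"]
        agg_rows = [r for r in table if r.lesion_label == "all"]
        assert len(lesion_rows) == 75
        assert len(agg_rows) == 15

    def test_summary_consistent_with_per_repeat_values(self, table):
        for r in table:
            if np.isnan(r.mean):
                continue
            vals = np.asarray(r.per_repeat_values)
            assert r.mean == pytest.approx(vals.mean())
            assert r.min == pytest.approx(vals.min())
            assert r.max == pytest.approx(vals.max())

    def test_frames_round_trip(self, table):
        long = metrics_to_frame(table)
        summary = summary_to_frame(table)
        assert set(long.columns) == {"metric", "sequence", "lesion", "repeat", "value"}
        assert len(summary) == len(table)

    def test_noiseless_input_gives_zero_sd_for_deterministic_metrics(self, compact_grids):
        series = {"clean": simulate_series(compact_grids, clean_protocol(
            n_repeats=3, temperature_schedule=(20.0,) * 3), master_seed=0)}
        table = metric_table(series)
        for r in table:
            if r.lesion_label == "all":
                continue  # pooled rows vary across lesion sizes by design
            if r.metric in ("ADC20", "ReCon", "GDR"):
                assert r.sd == pytest.approx(0.0, abs=1e-9)
            else:  # SNR/CNR undefined without noise
                assert np.isnan(r.mean)
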