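import numpy as np
import pytest

from nufd.core import FunctionalMap, TemporalSignal, amplitude_map
from nufd.diaphragm import relative_trace
from nufd.evaluate import deviation
from nufd.io_formats import RoiSpec
from nufd.normalize import (
    apply_factor,
    fit_signal_position_slope,
    roi_normalize,
    scaling_factor,
    standard_roi_grid,
)

DT = 0.31


def _sin_trace(amp_mm, n=220, f=0.25, offset=100.0):
    t = np.arange(n) * DT
    return relative_trace(offset + amp_mm * np.sin(2 * np.pi * f * t), DT)


class TestSlopeFit:
    def test_exact_linear_relation(self):
        x = np.linspace(-5, 5, 50)
        slope, intercept, r = fit_signal_position_slope(3.0 * x + 1.0, x)
        assert slope == pytest.approx(3.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_constant_position_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_signal_position_slope(np.arange(20.0), np.zeros(20))

    def test_weak_correlation_warns(self, rng):
        x = rng.normal(size=200)
        y = rng.normal(size=200)
        with pytest.warns(UserWarning, match="unreliable"):
            fit_signal_position_slope(y, x)


class TestScalingFactor:
    def test_direct_substitution(self):
        """slope 2 /mm, reference range 10 mm, signal range 40 => factor 0.5."""
        scan_x = _sin_trace(10.0)
        S = TemporalSignal(2.0 * scan_x.x, DT, component="ventilation")
        ref_x = _sin_trace(5.0)  # range 10 mm
        nf = scaling_factor(S, scan_x, ref_x)
        assert nf.factor == pytest.approx(0.5, rel=0.02)
        assert nf.components_identity() == pytest.approx(nf.factor, rel=1e-12)

    def test_identity_when_scan_equals_reference(self):
        scan_x = _sin_trace(7.5)
        S = TemporalSignal(-0.8 * scan_x.x, DT, component="ventilation")  # negative coupling
        nf = scaling_factor(S, scan_x, scan_x)
        assert nf.factor == pytest.approx(1.0, abs=0.02)

    def test_factor_inverse_in_scan_amplitude(self):
        ref_x = _sin_trace(7.5)
        factors = []
        for amp in (5.0, 10.0):
            scan_x = _sin_trace(amp)
            S = TemporalSignal(1.5 * scan_x.x, DT, component="ventilation")
            factors.append(scaling_factor(S, scan_x, ref_x).factor)
        assert factors[0] / factors[1] == pytest.approx(2.0, rel=0.03)

    def test_out_of_range_factor_clamped_with_warning(self):
        scan_x = _sin_trace(100.0)
        S = TemporalSignal(1.0 * scan_x.x, DT, component="ventilation")
        ref_x = _sin_trace(1.0)
        with pytest.warns(UserWarning, match="clamp"):
            nf = scaling_factor(S, scan_x, ref_x)
        assert nf.factor == 0.2 and nf.clamped

    def test_degenerate_signal_rejected(self):
        scan_x = _sin_trace(10.0)
        S = TemporalSignal(np.zeros(220), DT)
        with pytest.raises(ValueError):
            scaling_factor(S, scan_x, scan_x)


class TestApplyFactor:
    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_factor(np.ones(8), 0.0)

    def test_factor_one_is_identity(self, rng):
        sig = rng.normal(size=(20, 5))
        assert np.array_equal(apply_factor(sig, 1.0), sig)

    def test_order_equivalence_scaling_signals_vs_map(self, phantom_clean_processed):
        """Scaling the ventilation signals before the transform equals scaling
        the finished map, by linearity."""
        _, series, truth = phantom_clean_processed
        from nufd.io_formats import ImageSeries

        small = ImageSeries(series.frames[:, ::2, ::2], DT)
        mask = truth.lung_mask[::2, ::2]
        m1 = amplitude_map(small, mask, "ventilation", cutoff=0.775, signal_scale=0.5)
        m0 = amplitude_map(small, mask, "ventilation", cutoff=0.775)
        assert np.allclose(m1.values, 0.5 * m0.values, rtol=1e-10)
        assert m1.masked_mean() == pytest.approx(0.5 * m0.masked_mean(), rel=1e-10)


def _toy_map(rng, H=24, W=24):
    mask = np.zeros((H, W), bool)
    mask[4:20, 4:20] = True
    values = np.where(mask, rng.uniform(1.0, 3.0, (H, W)), 0.0)
    return FunctionalMap(values=values, mask=mask, kind="Vw")


class TestRoiNormalize:
    def test_division_by_roi_mean(self, rng):
        fmap = _toy_map(rng)
        roi = RoiSpec((6, 6), 8, label=1)
        roi_mean = fmap.values[roi.rows, roi.cols].mean()
        out = roi_normalize(fmap, roi)
        assert np.allclose(out.values[fmap.mask], fmap.values[fmap.mask] / roi_mean)
        assert out.values[roi.rows, roi.cols].mean() == pytest.approx(1.0, abs=1e-12)
        assert out.normalized_by[0] == "roi"

    def test_idempotence(self, rng):
        fmap = _toy_map(rng)
        roi = RoiSpec((6, 6), 8)
        once = roi_normalize(fmap, roi)
        twice = roi_normalize(once, roi)
        assert np.allclose(twice.values, once.values, rtol=1e-12, atol=0)

    def test_global_scale_cancels_exactly(self, rng):
        fmap = _toy_map(rng)
        scaled = FunctionalMap(values=fmap.values * 3.7, mask=fmap.mask, kind="Vw")
        roi = RoiSpec((8, 8), 8)
        delta, _ = deviation(roi_normalize(fmap, roi), roi_normalize(scaled, roi))
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_zero_roi_rejected(self):
        mask = np.ones((16, 16), bool)
        fmap = FunctionalMap(values=np.zeros((16, 16)), mask=mask, kind="Vw")
        with pytest.raises(ValueError, match="positive"):
            roi_normalize(fmap, RoiSpec((2, 2), 8))

    def test_roi_outside_mask_rejected(self, rng):
        fmap = _toy_map(rng)
        with pytest.raises(ValueError, match="non-mask"):
            roi_normalize(fmap, RoiSpec((0, 0), 8))


class TestStandardRoiGrid:
    @pytest.mark.parametrize("size", [8, 12])
    def test_six_rois_inside_phantom_mask(self, small_mask_phantom, size):
        _, truth = small_mask_phantom
        rois = standard_roi_grid(truth.lung_mask, size)
        assert [r.label for r in rois] == [1, 2, 3, 4, 5, 6]
        cover = np.zeros_like(truth.lung_mask, dtype=int)
        for r in rois:
            assert truth.lung_mask[r.rows, r.cols].all()
            cover[r.rows, r.cols] += 1
        assert cover.max() == 1  # non-overlapping

    def test_labels_follow_right_then_left_lung(self, small_mask_phantom):
        _, truth = small_mask_phantom
        rois = standard_roi_grid(truth.lung_mask, 8)
        right_cols = [r.origin[1] for r in rois[:3]]
        left_cols = [r.origin[1] for r in rois[3:]]
        assert max(right_cols) < min(left_cols)
        # top -> bottom within each lung
        assert rois[0].origin[0] < rois[1].origin[0] < rois[2].origin[0]

    def test_mirror_flip_swaps_lungs(self, small_mask_phantom):
        _, truth = small_mask_phantom
        rois = standard_roi_grid(truth.lung_mask, 8)
        flipped = standard_roi_grid(truth.lung_mask[:, ::-1], 8)
        W = truth.lung_mask.shape[1]
        for orig, flip in zip(rois[:3], flipped[3:]):
            assert abs(flip.origin[0] - orig.origin[0]) <= 1
            assert abs((W - flip.origin[1] - flip.width) - orig.origin[1]) <= 1

    def test_oversized_roi_rejected(self, small_mask_phantom):
        _, truth = small_mask_phantom
        with pytest.raises(ValueError, match="cannot place"):
            standard_roi_grid(truth.lung_mask, 40)
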