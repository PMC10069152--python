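"""Core NuFD operations against analytic signals and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nufd.core import (
    FrequencyTrack,
    RidgeError,
    TemporalSignal,
    amplitude_map,
    compute_virtual_times,
    determine_cutoff,
    mean_lung_signal,
    nonuniform_dft,
    nufft_spectrum,
    separate_components,
    track_instantaneous_frequency,
)
from nufd.io_formats import ImageSeries
from nufd.phantom import PhantomConfig, generate_phantom

DT = 0.31


def _times(n, dt=DT):
    return np.arange(n) * dt


def _xcorr_lag(a, b):
    return int(np.argmax(np.correlate(a, b, mode="full"))) - (len(a) - 1)


class TestMeanLungSignal:
    def test_constant_image(self):
        s = ImageSeries(np.full((4, 6, 6), 7.5), DT)
        mask = np.ones((6, 6), bool)
        assert np.allclose(mean_lung_signal(s, mask).values, 7.5)

    def test_single_pixel_mask(self, rng):
        frames = rng.uniform(0, 10, (5, 6, 6))
        mask = np.zeros((6, 6), bool)
        mask[2, 3] = True
        s = ImageSeries(frames, DT)
        assert np.array_equal(mean_lung_signal(s, mask).values, frames[:, 2, 3])

    def test_grid_mismatch(self, rng):
        s = ImageSeries(rng.uniform(0, 1, (3, 6, 6)), DT)
        with pytest.raises(ValueError, match="grid"):
            mean_lung_signal(s, np.ones((4, 4), bool))


class TestCutoff:
    def test_mixture_gives_in_band_valley(self):
        t = _times(220)
        v = np.sin(2 * np.pi * 0.25 * t) + 0.3 * np.sin(2 * np.pi * 1.2 * t)
        sig = TemporalSignal(v, DT)
        cut = determine_cutoff(sig)
        assert 0.55 <= cut <= 1.0
        spec = np.abs(np.fft.rfft(v - v.mean()))
        freqs = np.fft.rfftfreq(len(v), DT)
        mag_at = spec[np.argmin(np.abs(freqs - cut))]
        peak_resp = spec[np.argmin(np.abs(freqs - 0.25))]
        peak_card = spec[np.argmin(np.abs(freqs - 1.2))]
        assert mag_at < 0.1 * min(peak_resp, peak_card)

    def test_pure_low_tone_falls_back_to_midpoint(self):
        v = np.sin(2 * np.pi * 0.25 * _times(220))
        assert determine_cutoff(TemporalSignal(v, DT)) == pytest.approx(0.775)

    def test_white_noise_always_inside_band(self, rng):
        for _ in range(5):
            v = rng.normal(size=220)
            assert 0.55 <= determine_cutoff(TemporalSignal(v, DT)) <= 1.0

    def test_nyquist_too_low_rejected(self):
        v = np.sin(_times(100, dt=0.8))
        with pytest.raises(ValueError, match="Nyquist"):
            determine_cutoff(TemporalSignal(v, 0.8))


class TestSeparateComponents:
    def test_pure_low_tone_passes_through(self):
        t = _times(220)
        src = np.sin(2 * np.pi * 0.2 * t)
        vent, perf = separate_components(src, 0.7, DT)
        mid = slice(20, 200)
        amp_err = np.abs(vent[mid] - (src - src.mean())[mid]).max()
        assert amp_err < 0.01
        assert np.sqrt((perf[mid] ** 2).mean()) < 0.01

    def test_zero_phase_no_lag(self):
        t = _times(220)
        lo = np.sin(2 * np.pi * 0.2 * t)
        hi = 0.5 * np.sin(2 * np.pi * 1.2 * t)
        vent, perf = separate_components(lo + hi, 0.775, DT)
        assert _xcorr_lag(vent, lo) == 0
        assert _xcorr_lag(perf, hi) == 0

    def test_dc_only_input_vanishes(self):
        vent, perf = separate_components(np.full(128, 3.0), 0.7, DT)
        assert np.abs(vent).max() < 1e-9 and np.abs(perf).max() < 1e-9

    def test_cutoff_outside_range_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            separate_components(np.ones(64), 2.0, DT)


class TestRidge:
    def test_stationary_tone(self):
        v = np.sin(2 * np.pi * 0.25 * _times(220))
        tr = track_instantaneous_frequency(v, (0.1, 0.5), DT)
        assert np.abs(tr.frequencies - 0.25).max() <= 0.02

    def test_no_energy_in_band_raises(self, rng):
        v = np.sin(2 * np.pi * 0.25 * _times(220))
        with pytest.raises(RidgeError):
            track_instantaneous_frequency(v, (1.2, 1.5), DT)

    def test_track_must_stay_in_band(self):
        with pytest.raises(ValueError, match="band"):
            FrequencyTrack(np.full(10, 0.9), band=(0.1, 0.5))


class TestVirtualTimes:
    def test_constant_track_is_identity(self):
        t = _times(100)
        tr = FrequencyTrack(np.full(100, 0.25), band=(0.1, 0.5))
        vt = compute_virtual_times(tr, t)
        assert vt.f_c == pytest.approx(0.25)
        assert np.allclose(vt.times, t, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_strictly_increasing_for_any_positive_track(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(10, 200))
        f = r.uniform(0.05, 1.5, n)
        tr = FrequencyTrack(f, band=(0.05, 1.5))
        vt = compute_virtual_times(tr, _times(n))
        assert (np.diff(vt.times) > 0).all()


class TestNufft:
    def test_single_sample_flat_magnitude(self):
        spec = nufft_spectrum(np.array([2.0]), np.array([0.5]), 16, duration=10.0)
        assert np.allclose(np.abs(spec), np.abs(spec[0]), rtol=1e-9)

    def test_uniform_times_match_fft(self, rng):
        n = 220
        t = _times(n)
        v = rng.normal(size=n)
        fast = nufft_spectrum(v, t, 100)
        ref = 2.0 / n * np.fft.fft(v)[:100]
        assert np.abs(fast - ref).max() / np.abs(ref).max() <= 1e-9

    def test_unit_sinusoid_peak_is_one(self):
        n = 220
        t = _times(n)
        v = np.sin(2 * np.pi * (17 / (n * DT)) * t)
        spec = np.abs(nufft_spectrum(v, t, 110))
        assert spec[17] == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_direct_sum_on_random_instances(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(2, 257))
        t = np.sort(r.uniform(0, n * DT, n))
        t += np.arange(n) * 1e-9  # ensure strictly increasing
        v = r.normal(size=n)
        k = int(r.integers(4, 129))
        dur = n * float(np.mean(np.diff(t)))
        fast = nufft_spectrum(v, t, k, duration=dur)
        direct = nonuniform_dft(v, t, np.arange(k) / dur)
        assert np.abs(fast - direct).max() / np.abs(direct).max() <= 1e-9

    def test_invalid_inputs(self):
        with pytest.raises(ValueError, match="mismatch"):
            nufft_spectrum(np.ones(4), np.ones(5), 8)
        with pytest.raises(ValueError, match="n_modes"):
            nufft_spectrum(np.ones(4), _times(4), 3)


@pytest.fixture(scope="module")
def ratio_phantom():
    """Phantom with a ventilation field holding pixels at amplitude a and
    2a plus one silent pixel."""
    probe = PhantomConfig(n_frames=21, noise_sigma=0.0, seed=11, anatomy_seed=11)
    _, truth0 = generate_phantom(probe)
    field = np.where(truth0.lung_mask, 0.06, 0.0)
    pix = np.argwhere(truth0.lung_mask)
    p_a, p_2a, p_zero = pix[50], pix[120], pix[200]
    field[tuple(p_a)] = 0.05
    field[tuple(p_2a)] = 0.10
    field[tuple(p_zero)] = 0.0
    cfg = PhantomConfig(
        n_frames=240,
        noise_sigma=0.0,
        seed=11,
        anatomy_seed=11,
        ventilation_amplitude_field=field,
    )
    series, truth = generate_phantom(cfg)
    from nufd.preprocess import discard_steady_state

    vw = amplitude_map(discard_steady_state(series), truth.lung_mask, "ventilation")
    return vw, truth, (tuple(p_a), tuple(p_2a), tuple(p_zero))


class TestAmplitudeMap:
    def test_doubled_amplitude_doubles_map(self, ratio_phantom):
        vw, _, (p_a, p_2a, _) = ratio_phantom
        assert vw.values[p_2a] / vw.values[p_a] == pytest.approx(2.0, rel=0.02)

    def test_silent_pixel_is_dark(self, ratio_phantom):
        vw, truth, (_, _, p_zero) = ratio_phantom
        assert vw.values[p_zero] < 0.01 * np.median(vw.values[truth.lung_mask])

    def test_map_zero_outside_mask_and_nonnegative(self, ratio_phantom):
        vw, truth, _ = ratio_phantom
        assert np.all(vw.values[~truth.lung_mask] == 0)
        assert vw.values.min() >= 0

    def test_intensity_scaling_scales_map_linearly(self, phantom_clean_processed):
        _, series, truth = phantom_clean_processed
        small = ImageSeries(series.frames[:, ::2, ::2], DT)
        mask = truth.lung_mask[::2, ::2]
        m1 = amplitude_map(small, mask, "ventilation", cutoff=0.775)
        doubled = ImageSeries(small.frames * 2.0, DT)
        m2 = amplitude_map(doubled, mask, "ventilation", cutoff=0.775)
        assert np.allclose(m2.values, 2.0 * m1.values, rtol=1e-9)
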