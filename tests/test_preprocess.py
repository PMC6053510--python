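"""Gravity estimation, anatomical alignment, zero-lag filtering, bout detection."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import gaitspeed as gs
from gaitspeed.errors import AlignmentWarning, SignalQualityWarning, TooShortError
from gaitspeed.preprocess import (
    BoutConfig,
    FilterSpec,
    detect_walking_bouts,
    estimate_gravity,
    lowpass,
    tilt_correct_and_align,
)
from gaitspeed.signal_io import UniformRecording, resample_uniform

from conftest import make_activity_recording


def _uniform(data, rate=100.0):
    n = len(data)
    return UniformRecording(
        "s", np.datetime64("2023-05-01T09:00:00", "ns"), rate,
        np.asarray(data, dtype=float), np.arange(n) / rate, [],
    )


class TestEstimateGravity:
    def test_axis_aligned_constant(self):
        g = estimate_gravity(np.tile([0.0, 0.0, 1.0], (200, 1)))
        np.testing.assert_allclose(g, [0, 0, 1], atol=1e-12)

    def test_tilted_constant_is_normalised(self):
        g = estimate_gravity(np.tile([0.5, 0.0, 0.8660254], (200, 1)))
        np.testing.assert_allclose(np.linalg.norm(g), 1.0, atol=1e-12)
        np.testing.assert_allclose(g, [0.5, 0.0, 0.8660254], atol=1e-6)

    def test_noise_concentration_within_one_degree(self):
        # mean of 1000 samples with SD 0.02 g concentrates well inside 1 degree
        rng = np.random.default_rng(1)
        seg = np.tile([0.0, 0.0, 1.0], (1000, 1)) + rng.normal(0, 0.02, (1000, 3))
        g = estimate_gravity(seg)
        angle = np.degrees(np.arccos(np.clip(g @ [0, 0, 1], -1, 1)))
        assert angle < 1.0

    @pytest.mark.parametrize("scale", [0.3, 1.8])
    def test_implausible_magnitude_warns(self, scale):
        with pytest.warns(SignalQualityWarning):
            estimate_gravity(np.tile([0.0, 0.0, scale], (100, 1)))


class TestAlignment:
    def test_static_recording_zeroes_all_channels(self):
        rot = Rotation.from_euler("xyz", [20, -15, 40], degrees=True).as_matrix()
        data = np.tile([0.0, 0.0, 1.0], (500, 1)) @ rot.T
        with pytest.warns(AlignmentWarning):  # no horizontal structure
            sig = tilt_correct_and_align(_uniform(data), (0, 500))
        assert sig.gravity_removed
        np.testing.assert_allclose(sig.v, 0, atol=1e-9)
        np.testing.assert_allclose(sig.ml, 0, atol=1e-9)
        np.testing.assert_allclose(sig.ap, 0, atol=1e-9)

    def test_single_axis_horizontal_becomes_ap(self):
        rng = np.random.default_rng(2)
        n = 1000
        t = np.arange(n) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t) + 0.3 * np.sin(4 * np.pi * 2.0 * t - np.pi / 2)
        data = np.column_stack([x, np.zeros(n), np.ones(n) + rng.normal(0, 1e-4, n)])
        sig = tilt_correct_and_align(_uniform(data), (0, n))
        np.testing.assert_allclose(np.abs(sig.ap), np.abs(x), atol=0.01)
        assert np.std(sig.ml) < 0.01

    def test_rotation_of_device_frame_recovered(self, low_profile):
        """A simulated walk rotated arbitrarily yields the same anatomical
        channels as the unrotated recording (AP sign fixed by skewness)."""
        from conftest import replace_profile

        base = replace_profile(low_profile, tilt=np.eye(3), noise_sd=0.0)
        rec0, _ = gs.simulate_walk(base, 1.2, 30.0, seed=5)
        rot = Rotation.from_euler("xyz", [25, -10, 130], degrees=True).as_matrix()
        rotated = replace_profile(low_profile, tilt=rot, noise_sd=0.0)
        rec1, _ = gs.simulate_walk(rotated, 1.2, 30.0, seed=5)

        u0 = resample_uniform(rec0, 100.0)
        u1 = resample_uniform(rec1, 100.0)
        s0 = tilt_correct_and_align(u0, (0, u0.n_samples))
        s1 = tilt_correct_and_align(u1, (0, u1.n_samples))
        np.testing.assert_allclose(s1.ap, s0.ap, atol=5e-3)
        np.testing.assert_allclose(s1.v, s0.v, atol=5e-3)
        np.testing.assert_allclose(s1.ml, s0.ml, atol=5e-3)

    def test_gravity_removed_mean_near_zero_over_walk(self, walk_rest_recording):
        rec, window = walk_rest_recording
        uni = resample_uniform(rec, 100.0)
        sig = tilt_correct_and_align(uni, window)
        assert abs(np.mean(sig.v)) < 0.05


class TestLowpass:
    SPEC = FilterSpec(order=4, cutoff=20.0, zero_lag=True)

    def test_constant_series_unchanged(self):
        x = np.full(500, 0.7)
        np.testing.assert_allclose(lowpass(x, 100.0, self.SPEC), x, atol=1e-9)

    def test_stopband_attenuation_matches_two_pass_butterworth(self):
        # |H|^2 at 30 Hz for order 4, cutoff 20: (1 + (30/20)^8)^-1 = 0.03755;
        # sampled at 1 kHz so bilinear warping is negligible
        t = np.arange(40000) / 1000.0
        y = lowpass(np.sin(2 * np.pi * 30 * t), 1000.0, self.SPEC)
        amp = np.max(np.abs(y[10000:30000]))
        expected = 1.0 / (1.0 + 1.5**8)
        assert amp == pytest.approx(expected, rel=0.02)

    def test_passband_amplitude_and_zero_phase(self):
        t = np.arange(40000) / 1000.0
        x = np.sin(2 * np.pi * 2 * t)
        y = lowpass(x, 1000.0, self.SPEC)
        seg = slice(10000, 30000)
        assert np.max(np.abs(y[seg])) >= 0.999
        # zero-lag: the output is still at its maximum where the input peaks
        assert y[seg][np.argmax(x[seg])] >= 0.999

    def test_idempotent_on_band_limited_signal(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 3 * t)
        once = lowpass(x, 100.0, self.SPEC)
        twice = lowpass(once, 100.0, self.SPEC)
        # interior comparison: filtfilt edge transients dominate the margins
        np.testing.assert_allclose(twice[100:-100], once[100:-100], atol=1e-6)

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortError):
            lowpass(np.zeros(10), 100.0, self.SPEC)

    def test_cutoff_must_be_below_nyquist(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), 30.0, self.SPEC)


class TestBoutDetection:
    def test_flat_signal_yields_no_bouts(self):
        import warnings

        data = np.tile([0.0, 0.0, 1.0], (3000, 1))
        uni = _uniform(data)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", AlignmentWarning)
            aligned = tilt_correct_and_align(uni, (0, 3000))
        assert detect_walking_bouts(aligned) == []

    def test_single_walk_flanked_by_rest(self, walk_rest_recording):
        rec, window = walk_rest_recording
        uni = resample_uniform(rec, 100.0)
        bouts = gs.detect_bouts(uni)
        assert len(bouts) == 1
        b = bouts[0]
        assert abs(b.start_index - window[0]) <= 2 * 100
        assert abs(b.end_index - window[1]) <= 2 * 100

    def test_two_walks_with_rest_between(self, low_profile):
        rec, wins = make_activity_recording(
            low_profile,
            [("rest", 15.0), ("walk", 20.0, 1.2), ("rest", 10.0),
             ("walk", 20.0, 1.0), ("rest", 15.0)],
        )
        uni = resample_uniform(rec, 100.0)
        bouts = gs.detect_bouts(uni)
        assert len(bouts) == 2

    def test_minimum_duration_filters_short_activity(self, low_profile):
        rec, _ = make_activity_recording(
            low_profile, [("rest", 20.0), ("walk", 2.0, 1.2), ("rest", 20.0)]
        )
        uni = resample_uniform(rec, 100.0)
        bouts = gs.detect_bouts(uni, BoutConfig(min_duration=5.0))
        assert bouts == []
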