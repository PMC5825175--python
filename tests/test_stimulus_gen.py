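"""Stimulus generation: array geometry, truncated-Gaussian trains,
structured images, and the design matrix."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import kstest, truncnorm

import erfield as ef
from erfield.stimulus_gen import scale_image


class TestElectrodeArray:
    def test_paper_array_span(self):
        # 20 electrodes at 1 mm pitch span ~3.5 x 3.5 mm
        arr = ef.make_electrode_array(20, pitch_mm=1.0, diameter_um=400)
        width = np.ptp(arr.positions[:, 0])
        height = np.ptp(arr.positions[:, 1])
        assert 3.0 <= width <= 4.0
        assert 3.0 <= height <= 4.0
        assert arr.n_electrodes == 20

    def test_nearest_neighbour_pitch(self):
        for n in (7, 12, 20):
            arr = ef.make_electrode_array(n, pitch_mm=1.0)
            d = pdist(arr.positions)
            assert abs(d.min() - 1.0) < 1e-9
            # positions unique
            assert d.min() > 0

    def test_hex_flower(self):
        arr = ef.make_electrode_array(7, pitch_mm=1.0)
        centre = np.argmin(np.linalg.norm(arr.positions, axis=1))
        d = np.linalg.norm(arr.positions - arr.positions[centre], axis=1)
        assert np.allclose(np.sort(d)[1:], 1.0, atol=1e-9)

    def test_single_electrode(self):
        arr = ef.make_electrode_array(1)
        assert np.allclose(arr.positions, 0.0)

    @pytest.mark.parametrize("n,pitch", [(0, 1.0), (5, 0.0), (5, -1.0)])
    def test_invalid_arguments(self, n, pitch):
        with pytest.raises(ValueError):
            ef.make_electrode_array(n, pitch_mm=pitch)


class TestWhiteNoiseTrain:
    def test_truncated_sd_closed_form(self):
        # analytic SD of N(0, sigma) truncated at +-2 sigma
        sd = ef.truncated_gaussian_sd(150.0, 300.0)
        from scipy.stats import norm
        expected = 150.0 * math.sqrt(
            1.0 - 4.0 * norm.pdf(2.0) / (2.0 * norm.cdf(2.0) - 1.0))
        assert abs(sd - expected) < 1e-12

    def test_empirical_sd_matches_analytic(self):
        train = ef.sample_white_noise_train(10 ** 6, 1, sigma_ua=150.0,
                                            limit_ua=300.0, seed=5)
        emp = train.amplitudes.std()
        assert abs(emp / ef.truncated_gaussian_sd(150.0, 300.0) - 1.0) < 0.01

    def test_no_truncation_limit(self):
        train = ef.sample_white_noise_train(200000, 1, sigma_ua=150.0,
                                            limit_ua=1e9, seed=6)
        assert abs(train.amplitudes.std() / 150.0 - 1.0) < 0.01

    def test_limit_respected_and_deterministic(self):
        t1 = ef.sample_white_noise_train(5000, 4, seed=7)
        t2 = ef.sample_white_noise_train(5000, 4, seed=7)
        assert np.array_equal(t1.amplitudes, t2.amplitudes)
        assert np.abs(t1.amplitudes).max() <= 300.0

    def test_ks_against_truncated_gaussian(self):
        train = ef.sample_white_noise_train(100000, 1, seed=8)
        dist = truncnorm(-2.0, 2.0, loc=0.0, scale=150.0)
        stat, p = kstest(train.amplitudes.ravel(), dist.cdf)
        assert p > 0.01

    def test_invalid_sigma(self):
        with pytest.raises(ValueError):
            ef.sample_white_noise_train(10, 1, sigma_ua=0.0)


class TestStructuredImages:
    def test_spots_extrema_and_scaling(self, rng):
        img = ef.render_structured_image("spots", rng)
        assert img.pixels.shape == (500, 500)
        assert np.abs(img.pixels).max() == pytest.approx(250.0)

    def test_scaling_idempotent(self, rng):
        img = ef.render_structured_image("lines", rng)
        again = scale_image(img.pixels)
        assert np.array_equal(img.pixels, again)

    def test_grating_below_nyquist(self, rng):
        # 1 mm electrode pitch -> spatial frequency < 0.5 cyc/mm
        img = ef.render_structured_image("static_grating", rng)
        spec = np.abs(np.fft.fft2(img.pixels))
        spec[0, 0] = 0.0
        freqs = np.fft.fftfreq(500, d=0.01)   # cycles per mm
        iy, ix = np.unravel_index(np.argmax(spec), spec.shape)
        peak_freq = math.hypot(freqs[iy], freqs[ix])
        assert peak_freq < 0.5

    def test_moving_grating_frame_count(self, rng):
        frames = ef.render_structured_image("moving_grating", rng,
                                            pulse_rate_hz=30.0)
        assert len(frames) == 9                 # 300 ms x 30 Hz
        peak = max(np.abs(f.pixels).max() for f in frames)
        assert peak == pytest.approx(250.0)

    def test_unknown_mode(self, rng):
        with pytest.raises(ValueError):
            ef.render_structured_image("checkerboard", rng)


class TestImageToAmplitudes:
    def test_constant_field(self, rng):
        arr = ef.make_electrode_array(7)
        img = ef.StimulusImage(pixels=np.full((500, 500), 42.0), mode="spots")
        assert np.allclose(ef.image_to_pulse_amplitudes(img, arr), 42.0)

    def test_zero_image(self, rng):
        arr = ef.make_electrode_array(7)
        img = ef.StimulusImage(pixels=np.zeros((500, 500)), mode="spots")
        assert np.allclose(ef.image_to_pulse_amplitudes(img, arr), 0.0)

    def test_delta_image_hits_one_electrode(self):
        arr = ef.make_electrode_array(7)
        img = ef.StimulusImage(pixels=np.zeros((500, 500)), mode="spots")
        # electrode 0 centre -> pixel indices
        x, y = arr.positions[0]
        row = int(np.round(249.5 + y / 0.01))
        col = int(np.round(249.5 + x / 0.01))
        img.pixels[row, col] = 99.0
        amps = ef.image_to_pulse_amplitudes(img, arr)
        assert amps[0] == 99.0
        assert np.count_nonzero(amps) == 1

    def test_out_of_bounds_electrode(self):
        arr = ef.make_electrode_array(1)
        arr = ef.ElectrodeArray(positions=np.array([[10.0, 0.0]]),
                                diameter_um=400.0)
        img = ef.StimulusImage(pixels=np.zeros((500, 500)), mode="spots")
        with pytest.raises(ValueError, match="electrode 0"):
            ef.image_to_pulse_amplitudes(img, arr)


class TestDesignMatrix:
    @pytest.mark.parametrize("freq,expected_L", [(10.0, 3), (20.0, 6), (30.0, 9)])
    def test_lag_count(self, freq, expected_L):
        train = ef.sample_white_noise_train(100, 2, frequency_hz=freq, seed=1)
        dm = ef.build_design_matrix(train, window_ms=300.0)
        assert dm.L == expected_L

    def test_row_count_and_lag0_block(self):
        train = ef.sample_white_noise_train(100, 3, frequency_hz=10.0, seed=2)
        dm = ef.build_design_matrix(train, window_ms=300.0)
        assert dm.n_responses == 98                      # 100 - L + 1
        assert np.array_equal(dm.rows[0, :3], train.amplitudes[dm.L - 1])
        assert np.array_equal(dm.rows[-1, :3], train.amplitudes[-1])

    def test_round_trip_recovers_pulses(self):
        train = ef.sample_white_noise_train(50, 4, frequency_hz=10.0, seed=3)
        dm = ef.build_design_matrix(train, window_ms=300.0)
        for t in range(dm.n_responses):
            stacked = dm.unstack(dm.rows[t])
            for lag in range(dm.L):
                assert np.array_equal(stacked[lag],
                                      train.amplitudes[t + dm.L - 1 - lag])

    def test_lag_labels(self):
        train = ef.sample_white_noise_train(50, 2, frequency_hz=20.0, seed=4)
        dm = ef.build_design_matrix(train, window_ms=300.0)
        assert np.allclose(dm.lag_times_ms, [0, -50, -100, -150, -200, -250])

    def test_window_too_short(self):
        train = ef.sample_white_noise_train(50, 2, frequency_hz=10.0, seed=5)
        with pytest.raises(ValueError):
            ef.build_design_matrix(train, window_ms=50.0)


@pytest.mark.parametrize("seed", [0, 3, 5])
def test_spots_have_up_to_four_local_extrema(seed):
    """A spots image contains between 1 and 4 blurred extremal regions
    (large spots keep a flat plateau after blurring, so connected regions
    of the local-maximum mask are counted, not pixels)."""
    from scipy.ndimage import label, maximum_filter
    rng = np.random.default_rng(seed)
    img = ef.render_structured_image("spots", rng)
    mag = np.abs(img.pixels)
    local_max = (mag == maximum_filter(mag, size=51)) & (mag > 25.0)
    _, n_extrema = label(local_max)
    assert 1 <= n_extrema <= 4
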