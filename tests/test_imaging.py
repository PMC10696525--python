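"""Image-stack processing: averaging, differentials, deconvolution, detection."""

import numpy as np
import pandas as pd
import pytest

from evprofile import imaging, synth
from evprofile.imaging import FrameStack


def _const_stack(value, n=20, shape=(16, 16), fps=10.0):
    return FrameStack(np.full((n,) + shape, float(value)), fps=fps)


class TestMovingAverage:
    def test_constant_stack_unchanged(self):
        out = imaging.moving_average(_const_stack(3.5), n=7)
        assert np.allclose(out.frames, 3.5)
        assert len(out) == 20 - 7 + 1

    def test_window_means_on_ramp(self):
        """Frames valued 1..20 with n=5: window means are 3.0, ..., 18.0."""
        frames = np.arange(1, 21, dtype=float)[:, None, None] * np.ones((1, 4, 4))
        out = imaging.moving_average(FrameStack(frames, fps=1.0), n=5)
        assert np.allclose(out.frames[0], 3.0)
        assert np.allclose(out.frames[15], 18.0)
        assert len(out) == 16

    def test_short_stack_raises(self):
        with pytest.raises(ValueError):
            imaging.moving_average(_const_stack(1.0, n=5), n=10)


class TestDifferentialStack:
    def test_static_scene_gives_zero_differentials(self):
        out = imaging.differential_stack(_const_stack(7.0))
        assert np.allclose(out.frames, 0.0)
        assert len(out) == 19

    def test_step_appears_in_exactly_one_differential(self):
        """A particle appearing between averaged frames j and j+1."""
        psf = synth.airy_psf(9)
        frames = np.zeros((6, 21, 21))
        frames[3:, 6:15, 6:15] = 4.0 * psf
        out = imaging.differential_stack(FrameStack(frames, fps=1.0))
        nonzero = [i for i in range(len(out)) if np.any(out.frames[i])]
        assert nonzero == [2]
        assert np.allclose(out.frames[2, 6:15, 6:15], 4.0 * psf)

    def test_single_frame_raises(self):
        with pytest.raises(ValueError):
            imaging.differential_stack(_const_stack(1.0, n=1))


class TestBuildPsf:
    def test_identical_inputs_return_normalized_input(self):
        img = synth.airy_psf(11) * 7.0
        out = imaging.build_psf([img] * 5)
        assert np.allclose(out, img / img.max())

    def test_shifted_copies_recover_kernel_centre(self):
        kernel = synth.airy_psf(11)
        base = np.zeros((31, 31))
        base[10:21, 10:21] = kernel
        rng = np.random.default_rng(0)
        images = [np.roll(base, tuple(rng.integers(-3, 4, 2)), axis=(0, 1)) for _ in range(30)]
        out = imaging.build_psf(images)
        assert np.allclose(out[10:21, 10:21], kernel, atol=1e-12)

    def test_needs_at_least_two_images(self):
        with pytest.raises(ValueError):
            imaging.build_psf([np.ones((5, 5))])


class TestDeconvolution:
    def test_delta_psf_is_identity(self, rng):
        img = rng.normal(size=(32, 32))
        delta = np.zeros((5, 5))
        delta[2, 2] = 1.0
        out = imaging.deconvolve_kspace(img, delta, regularization=1e-12)
        assert np.max(np.abs(out - img)) < 1e-6 * np.abs(img).max()

    @pytest.mark.parametrize("shift", [(0, 0), (3, -2), (-5, 7)])
    def test_round_trip_restores_peak(self, shift):
        from scipy.signal import fftconvolve

        psf = synth.airy_psf(11, 3.0)
        img = np.zeros((48, 48))
        r, c = 24 + shift[0], 24 + shift[1]
        img[r, c] = 10.0
        blurred = fftconvolve(img, psf, mode="same")
        # noise-free round trip: regularization far below the OTF power floor
        eps = 1e-10 * psf.sum() ** 2  # max |F(psf)|^2 is the DC term
        out = imaging.deconvolve_kspace(blurred, psf, regularization=eps)
        assert np.unravel_index(np.argmax(out), out.shape) == (r, c)
        assert abs(out[r, c] - 10.0) < 0.5  # amplitude within 5%
        # the default regularization still restores the position exactly
        out_default = imaging.deconvolve_kspace(blurred, psf)
        assert np.unravel_index(np.argmax(out_default), out_default.shape) == (r, c)

    def test_large_regularization_kills_output(self, rng):
        img = rng.normal(size=(16, 16))
        out = imaging.deconvolve_kspace(img, synth.airy_psf(7), regularization=1e12)
        assert np.abs(out).max() < 1e-9 * np.abs(img).max()

    def test_zero_psf_raises(self):
        with pytest.raises(ValueError):
            imaging.deconvolve_kspace(np.ones((8, 8)), np.zeros((3, 3)))


class TestParticleIntensity:
    def test_uniform_image(self):
        assert imaging.particle_intensity(np.full((9, 9), 2.5), (4, 4)) == 2.5

    def test_three_by_three_mean(self):
        img = np.zeros((7, 7))
        img[2:5, 2:5] = np.arange(1, 10).reshape(3, 3)
        assert imaging.particle_intensity(img, (3, 3)) == 5.0  # 45 / 9

    def test_border_peak_raises(self):
        with pytest.raises(ValueError):
            imaging.particle_intensity(np.ones((5, 5)), (0, 0))


def _render_landings(n_events, snr, seed, n_frames=140, shape=96, n_avg=10, fps=10.0):
    rng = np.random.default_rng(seed)
    sigma = 1.0
    amp = snr * sigma * np.sqrt(2 * n_avg)
    frames = rng.choice(np.arange(n_avg + 1, n_frames - n_avg - 1), n_events, replace=False)
    pos = []
    while len(pos) < n_events:
        p = rng.integers(10, shape - 10, size=2)
        if all(max(abs(p[0] - q[0]), abs(p[1] - q[1])) > 13 for q in pos):
            pos.append(p)
    pos = np.asarray(pos)
    ev = pd.DataFrame(
        {"time_s": frames / fps, "x_px": pos[:, 1], "y_px": pos[:, 0], "intensity": amp}
    )
    stack, _ = synth.render_image_stack(
        ev, (shape, shape), fps, synth.airy_psf(11, 3.0), sigma, seed + 1, n_frames=n_frames
    )
    return FrameStack(stack, fps=fps), set(map(int, frames)), pos


class TestDetectLandings:
    def test_empty_stack_empty_result(self):
        out = imaging.process_stack(_const_stack(0.0, n=15))
        assert out == []

    def test_recovers_injected_landings_with_exact_frames(self):
        stack, true_frames, _ = _render_landings(12, snr=10.0, seed=5)
        events = imaging.process_stack(stack, n_avg=10)
        assert len(events) == 12
        assert {e.frame for e in events} == true_frames
        times = [e.time_s for e in events]
        assert times == sorted(times)

    def test_recall_non_decreasing_in_snr(self):
        recalls = []
        for snr in (2.0, 10.0):
            stack, true_frames, _ = _render_landings(12, snr=snr, seed=9)
            events = imaging.process_stack(stack, n_avg=10)
            hits = sum(1 for e in events if e.frame in true_frames)
            recalls.append(hits / 12)
        assert recalls[1] >= recalls[0]
        assert recalls[1] == 1.0

    def test_intensity_rescaled_to_raw_units(self):
        """3x3-mean intensity, rescaled by n_avg, tracks the injected amplitude."""
        stack, _, pos = _render_landings(5, snr=40.0, seed=11)
        events = imaging.process_stack(stack, n_avg=10)
        psf = synth.airy_psf(11, 3.0)
        amp = 40.0 * np.sqrt(20)
        expected = amp * psf[4:7, 4:7].mean()  # 3x3 around the peak
        for e in events:
            assert abs(e.intensity - expected) / expected < 0.25


class TestTiffRoundTrip:
    def test_write_read_round_trip(self, tmp_path, rng):
        stack = FrameStack(rng.normal(size=(4, 8, 8)), fps=25.0)
        path = tmp_path / "stack.tif"
        imaging.write_stack(stack, path)
        back = imaging.read_stack(path)
        assert back.fps == 25.0
        assert np.allclose(back.frames, stack.frames, atol=1e-3)
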