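"""Spectral amplitude maps against brute-force DFT oracles."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alffpipe.spectral import (
    amplitude_spectrum,
    band_amplitude,
    compute_alff_map,
    compute_falff_map,
    gaussian_smooth,
    linear_detrend,
)

import _oracles
from conftest import centered_cosine, make_run

N, TR = 162, 2.0


def cosine_at_bin(k, n=N, tr=TR, amp=1.0):
    # midpoint-centred phase: detrend-invariant, single exact DFT bin
    return centered_cosine(k, n, amp)


class TestLinearDetrend:
    def test_removes_exact_line(self):
        t = np.arange(N, dtype=float)
        np.testing.assert_allclose(linear_detrend(3.0 + 0.5 * t), 0.0, atol=1e-9)

    def test_residual_mean_and_slope_zero(self, rng):
        x = rng.standard_normal(N)
        r = linear_detrend(x)
        assert abs(r.mean()) < 1e-12 * np.abs(x).max()
        t = np.arange(N) - (N - 1) / 2
        assert abs(r @ t) < 1e-8 * np.abs(x).max() * N

    def test_matches_polyfit_oracle(self, rng):
        x = rng.standard_normal(N) * 5 + 100
        np.testing.assert_allclose(linear_detrend(x), _oracles.detrend(x), atol=1e-9)

    def test_in_band_cosine_barely_changed(self):
        x = cosine_at_bin(16)
        a_before = _oracles.band_amplitude(x, TR, 0.01, 0.08)
        a_after = _oracles.band_amplitude(linear_detrend(x), TR, 0.01, 0.08)
        assert abs(a_after - a_before) / a_before < 0.005


class TestAmplitudeSpectrum:
    def test_pure_cosine_unit_amplitude(self):
        spec = amplitude_spectrum(cosine_at_bin(16), TR)
        assert spec.amplitudes[16] == pytest.approx(1.0, abs=1e-10)
        others = np.delete(spec.amplitudes, 16)
        assert np.all(others < 1e-10)

    def test_matches_brute_force_dft(self, rng):
        x = rng.standard_normal(50)
        spec = amplitude_spectrum(x, TR)
        np.testing.assert_allclose(spec.amplitudes, _oracles.dft_amplitudes(x), atol=1e-10)

    def test_freq_axis(self):
        spec = amplitude_spectrum(np.zeros(N), TR)
        assert spec.freqs[0] == 0.0
        assert spec.nyquist_hz == pytest.approx(1.0 / (2 * TR))
        assert np.all(np.diff(spec.freqs) > 0)

    def test_parseval(self, rng):
        # variance of the series equals summed power over all frequencies
        for _ in range(50):
            x = rng.standard_normal(64)
            lhs = np.sum(x**2)
            rhs = np.sum(np.abs(np.fft.fft(x)) ** 2) / len(x)
            assert abs(lhs - rhs) / lhs < 1e-10


class TestBandAmplitude:
    def test_band_bin_enumeration(self):
        # at N=162, TR=2 the inclusive band 0.01..0.08 Hz covers bins 4..25
        freqs = np.fft.rfftfreq(N, d=TR)
        in_band = [k for k, f in enumerate(freqs) if 0.01 <= round(f, 12) <= 0.08]
        assert in_band == list(range(4, 26))
        assert len(in_band) == 22

    def test_single_in_band_cosine(self):
        spec = amplitude_spectrum(cosine_at_bin(10), TR)
        assert band_amplitude(spec) == pytest.approx(1.0 / 22, rel=1e-9)

    def test_zero_spectrum(self):
        spec = amplitude_spectrum(np.zeros(N), TR)
        assert band_amplitude(spec) == 0.0

    def test_empty_band_errors(self):
        spec = amplitude_spectrum(np.zeros(16), 0.1)  # bins at 0.625 Hz spacing
        with pytest.raises(ValueError, match="band"):
            band_amplitude(spec, 0.01, 0.08)


class TestAlffMap:
    def test_two_voxel_worked_example(self):
        # voxels with band amplitudes in ratio 2:1 -> normalised {4/3, 2/3}
        data = np.zeros((2, 1, 1, N))
        data[0, 0, 0] = cosine_at_bin(10, amp=2.0)
        data[1, 0, 0] = cosine_at_bin(10, amp=1.0)
        run = make_run(data=data, tr=TR)
        alff, raw = compute_alff_map(run)
        np.testing.assert_allclose(
            alff.values[:, 0, 0], [4.0 / 3.0, 2.0 / 3.0], rtol=1e-9
        )
        np.testing.assert_allclose(raw.values[:, 0, 0], [2.0 / 22, 1.0 / 22], rtol=1e-9)

    def test_in_brain_mean_is_one(self, rng):
        run = make_run(rng=rng)
        alff, _ = compute_alff_map(run)
        assert alff.values[run.brain_mask].mean() == pytest.approx(1.0, abs=1e-12)

    def test_identical_voxels_give_unit_map(self):
        series = cosine_at_bin(10) + cosine_at_bin(40, amp=0.3)
        data = np.tile(series, (3, 3, 3, 1))
        alff, _ = compute_alff_map(make_run(data=data, tr=TR))
        np.testing.assert_allclose(alff.values, 1.0, rtol=1e-9)

    def test_scale_invariance(self, rng):
        data = 100 + rng.standard_normal((4, 4, 4, N))
        a1, _ = compute_alff_map(make_run(data=data, tr=TR))
        a2, _ = compute_alff_map(make_run(data=data * 7.3, tr=TR))
        np.testing.assert_allclose(a1.values, a2.values, rtol=1e-9)

    def test_pipeline_matches_oracle_on_random_series(self, rng):
        # the full detrend->FFT->band-mean path against the O(N^2) oracle
        data = rng.standard_normal((20, 1, 1, N)) * 3 + 50
        run = make_run(data=data, tr=TR)
        _, raw = compute_alff_map(run)
        for v in range(20):
            expected = _oracles.band_amplitude(
                _oracles.detrend(data[v, 0, 0]), TR, 0.01, 0.08
            )
            assert abs(raw.values[v, 0, 0] - expected) <= 1e-8 * max(expected, 1e-30)


class TestFalffMap:
    def test_in_band_cosine_gives_one(self):
        data = cosine_at_bin(10).reshape(1, 1, 1, N)
        fmap = compute_falff_map(make_run(data=data, tr=TR))
        assert fmap.values[0, 0, 0] == pytest.approx(1.0, abs=1e-10)

    def test_out_of_band_cosine_gives_zero(self):
        # 0.2 Hz = bin 64.8/162... use exact bin 65 (0.2006 Hz), out of band
        data = cosine_at_bin(65).reshape(1, 1, 1, N)
        fmap = compute_falff_map(make_run(data=data, tr=TR))
        assert fmap.values[0, 0, 0] == pytest.approx(0.0, abs=1e-10)

    def test_bounds_on_random_data(self, rng):
        run = make_run(rng=rng)
        fmap = compute_falff_map(run)
        vals = fmap.values[run.brain_mask]
        assert vals.min() >= 0.0 and vals.max() <= 1.0

    def test_adding_out_of_band_power_decreases_falff_keeps_alff(self):
        base = cosine_at_bin(10) + cosine_at_bin(20, amp=0.5)
        data = np.stack([base, base + cosine_at_bin(60, amp=2.0)]).reshape(2, 1, 1, N)
        run = make_run(data=data, tr=TR)
        fmap = compute_falff_map(run)
        _, raw = compute_alff_map(run)
        assert fmap.values[1, 0, 0] < fmap.values[0, 0, 0]
        assert raw.values[1, 0, 0] == pytest.approx(raw.values[0, 0, 0], rel=1e-9)

    def test_scale_invariance_per_voxel(self, rng):
        x = rng.standard_normal(N)
        data = np.stack([x, 5.0 * x]).reshape(2, 1, 1, N)
        fmap = compute_falff_map(make_run(data=data, tr=TR))
        assert fmap.values[0, 0, 0] == pytest.approx(fmap.values[1, 0, 0], rel=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_falff_always_in_unit_interval(self, seed):
        data = np.random.default_rng(seed).standard_normal((3, 2, 2, 24))
        run = make_run(data=data, tr=TR, n_frames=24)
        vals = compute_falff_map(run, 0.01, 0.08).values
        assert vals.min() >= 0.0 and vals.max() <= 1.0


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, rng):
        run = make_run(rng=rng)
        amap, _ = compute_alff_map(run)
        out = gaussian_smooth(amap, 0.0)
        np.testing.assert_array_equal(out.values, amap.values)

    def test_interior_constant_block_unchanged_at_centre(self):
        from alffpipe.spectral import AmplitudeMap

        vol = np.ones((11, 11, 11))
        amap = AmplitudeMap(
            values=vol, kind="A_raw", brain_mask=np.ones_like(vol, dtype=bool),
            voxel_sizes_mm=(3.0, 3.0, 3.0),
        )
        out = gaussian_smooth(amap, 3.0)  # sigma ~0.42 voxels, support well inside
        assert out.values[5, 5, 5] == pytest.approx(1.0, abs=1e-6)

    def test_impulse_matches_direct_convolution(self):
        from alffpipe.spectral import AmplitudeMap

        vol = np.zeros((11, 11, 11))
        vol[5, 5, 5] = 1.0
        amap = AmplitudeMap(
            values=vol, kind="A_raw", brain_mask=np.ones_like(vol, dtype=bool),
            voxel_sizes_mm=(3.0, 3.0, 3.0),
        )
        fwhm = 8.0
        sigma_vox = fwhm / (3.0 * 2 * np.sqrt(2 * np.log(2)))
        expected = _oracles.gaussian_convolve(vol, [sigma_vox] * 3)
        out = gaussian_smooth(amap, fwhm)
        np.testing.assert_allclose(out.values, expected, atol=2e-4)
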