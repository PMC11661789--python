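"""Spectrum preparation: Fourier cropping, tiling, background, EPA, scaling."""

import numpy as np
import pytest

from thonring.ctf_model import CtfParams, chi
from thonring.spectrum import (
    PowerSpectrum2D,
    RadialProfile,
    crop_square,
    equiphase_average,
    fourier_crop,
    radial_average,
    scale_profile_for_thickness_display,
    subtract_background_box,
    tile_average_spectrum,
)


class TestFourierCrop:
    def test_identity_at_nyquist(self):
        img = np.random.default_rng(0).standard_normal((256, 256))
        out, px = fourier_crop(img, 1.0, 2.0)
        assert out is img and px == 1.0

    def test_box_arithmetic_and_pixel_size(self):
        img = np.random.default_rng(1).standard_normal((512, 512))
        out, px = fourier_crop(img, 1.0, 5.0)
        assert out.shape == (204, 204)  # even-rounded 512 * 2/5
        assert px == pytest.approx(512 / 204, rel=1e-9)
        assert px == pytest.approx(2.5, rel=0.02)

    def test_mean_preserved(self):
        img = np.random.default_rng(2).standard_normal((256, 256)) + 7.5
        out, _ = fourier_crop(img, 1.0, 6.0)
        assert out.mean() == pytest.approx(img.mean(), rel=1e-6)

    def test_finer_than_achievable_is_noop(self):
        img = np.zeros((128, 128))
        out, px = fourier_crop(img, 1.0, 1.0)
        assert out.shape == (128, 128) and px == 1.0


class TestCropSquare:
    def test_square_even_input_unchanged(self):
        img = np.arange(256 * 256, dtype=float).reshape(256, 256)
        assert crop_square(img) is not None
        np.testing.assert_array_equal(crop_square(img), img)

    def test_rectangular_center_crop(self):
        img = np.random.default_rng(3).standard_normal((300, 212))
        out = crop_square(img)
        assert out.shape == (212, 212)
        np.testing.assert_array_equal(out, img[44:256, :])

    def test_odd_side_trimmed_even(self):
        assert crop_square(np.zeros((131, 131))).shape == (130, 130)


class TestTileAverage:
    def test_constant_image_zero_outside_dc(self):
        ps = tile_average_spectrum(np.full((256, 256), 3.0), 128, 1.0)
        amp = ps.amplitudes.copy()
        amp[128 // 2, 128 // 2] = 0.0
        assert np.abs(amp).max() < 1e-10

    def test_sinusoid_peak_at_its_frequency(self):
        n, f = 256, 16 / 128.0  # 16 cycles per 128-px tile along x
        x = np.arange(n)
        img = np.cos(2 * np.pi * f * x)[None, :].repeat(n, axis=0)
        ps = tile_average_spectrum(img, 128, 1.0)
        c = 64
        peak = np.unravel_index(np.argmax(ps.amplitudes), ps.amplitudes.shape)
        assert peak in {(c, c + 16), (c, c - 16)}

    def test_white_noise_spectrum_flat_in_expectation(self):
        rng = np.random.default_rng(4)
        img = rng.standard_normal((512, 512))
        ps = tile_average_spectrum(img, 128, 1.0)
        g, _ = ps.frequency_grids()
        inner = ps.amplitudes[(g > 0.1) & (g < 0.2)]
        outer = ps.amplitudes[(g > 0.3) & (g < 0.4)]
        assert inner.mean() == pytest.approx(outer.mean(), rel=0.05)


class TestBackground:
    def test_constant_spectrum_to_zero(self):
        ps = PowerSpectrum2D(np.full((128, 128), 2.0), 1.0)
        out = subtract_background_box(ps)
        assert out.background_subtracted
        assert np.abs(out.amplitudes).max() < 1e-12

    def test_linear_ramp_removed_away_from_edges(self):
        y, x = np.mgrid[0:128, 0:128]
        ps = PowerSpectrum2D(0.01 * x + 0.02 * y, 1.0)
        out = subtract_background_box(ps, box_radius=8).amplitudes
        assert np.abs(out[16:-16, 16:-16]).max() < 1e-9

    def test_fast_oscillation_survives(self):
        x = np.arange(128)
        osc = np.sin(2 * np.pi * x / 4.0)  # period 4 px << box width 17
        ps = PowerSpectrum2D(np.tile(osc, (128, 1)), 1.0)
        out = subtract_background_box(ps, box_radius=8).amplitudes
        assert out[:, 20:-20].max() >= 0.9 * osc.max()


def _model_spectrum(box, px, optics, ctf):
    """sin^2(chi) rendered on a spectrum grid."""
    ps = PowerSpectrum2D(np.zeros((box, box)), px, background_subtracted=True)
    g, ang = ps.frequency_grids()
    ps.amplitudes = np.sin(chi(g, ang, optics, ctf)) ** 2
    return ps


class TestEquiphaseAverage:
    def test_identity_without_astigmatism(self, optics):
        ctf = CtfParams(10000.0, 10000.0)
        ps = _model_spectrum(256, 1.0, optics, ctf)
        epa = equiphase_average(ps, ctf, optics)
        plain = radial_average(ps)
        band = (epa.freqs > 0.05) & (epa.freqs < 0.4)
        assert np.allclose(epa.amplitudes[band], plain.amplitudes[band], atol=5e-3)

    def test_epa_restores_ring_contrast(self, optics):
        # 1000 A astigmatism blurs the plain radial average at high rings
        ctf = CtfParams(10500.0, 9500.0, 30.0)
        ps = _model_spectrum(512, 1.0, optics, ctf)
        epa = equiphase_average(ps, ctf, optics)
        plain = radial_average(ps)
        lam = optics.wavelength
        g5 = np.sqrt(5.0 / (lam * ctf.defocus_mean))  # ~5th zero
        sel = (epa.freqs > g5 * 0.95) & (epa.freqs < g5 * 1.3)
        contrast = lambda p: p.amplitudes[sel].max() - p.amplitudes[sel].min()
        assert contrast(epa) > contrast(plain)

    def test_epa_self_consistency_with_mean_defocus_model(self, optics):
        ctf = CtfParams(10500.0, 9500.0, 30.0)
        ps = _model_spectrum(512, 1.0, optics, ctf)
        epa = equiphase_average(ps, ctf, optics)
        mean = CtfParams(ctf.defocus_mean, ctf.defocus_mean)
        band = (epa.freqs > 0.05) & (epa.freqs < 0.35)
        model = np.sin(chi(epa.freqs[band], 0.0, optics, mean)) ** 2
        assert np.abs(epa.amplitudes[band] - model).mean() < 0.01

    def test_missing_fit_falls_back_to_radial(self, optics):
        ps = _model_spectrum(128, 1.0, optics, CtfParams(9000.0, 9000.0))
        epa = equiphase_average(ps, None, optics)
        np.testing.assert_allclose(epa.amplitudes, radial_average(ps).amplitudes)


class TestThicknessDisplayScaling:
    def test_constant_profile_maps_to_half(self):
        prof = RadialProfile(np.linspace(0, 0.5, 100), np.zeros(100))
        out = scale_profile_for_thickness_display(prof)
        np.testing.assert_allclose(out.amplitudes, 0.5)

    def test_oscillation_centered_on_half_in_unit_range(self):
        f = np.linspace(0, 0.5, 400)
        prof = RadialProfile(f, 3.0 * np.sin(2 * np.pi * 40 * f))
        out = scale_profile_for_thickness_display(prof)
        assert out.amplitudes.min() >= 0.0 and out.amplitudes.max() <= 1.0
        mid = out.amplitudes[50:-50]
        assert mid.mean() == pytest.approx(0.5, abs=0.05)
        assert mid.max() > 0.9 and mid.min() < 0.1
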