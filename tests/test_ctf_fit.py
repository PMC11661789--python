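"""CTF fitting: NCC scoring, 1D search, 2D refinement, goodness of fit."""

import numpy as np
import pytest

from thonring.ctf_fit import (
    fit_resolution,
    goodness_of_fit_curve,
    model_profile,
    ncc_score,
    refine_2d,
    search_defocus_1d,
    score_spectrum_2d,
)
from thonring.ctf_model import CtfParams, chi, ctf_thin
from thonring.spectrum import (
    PowerSpectrum2D,
    RadialProfile,
    radial_average,
    subtract_background_box,
    tile_average_spectrum,
)
from thonring.synthetic import SyntheticSpec, synth_micrograph


def _profile_for(optics, defocus, noise=0.0, seed=0, n=400):
    freqs = np.linspace(0.02, 0.3, n)
    amps = np.abs(ctf_thin(freqs, 0.0, optics, CtfParams(defocus, defocus)))
    if noise:
        amps = amps + np.random.default_rng(seed).normal(0, noise, n)
    return RadialProfile(freqs, amps)


class TestNcc:
    def test_self_and_negated(self):
        x = np.sin(np.linspace(0, 20, 100))
        assert ncc_score(x, x) == pytest.approx(1.0)
        assert ncc_score(x, -x) == pytest.approx(-1.0)

    def test_degenerate_scores_zero(self):
        assert ncc_score(np.ones(50), np.sin(np.linspace(0, 5, 50))) == 0.0

    def test_declines_with_defocus_mismatch(self, optics):
        freqs = np.linspace(1 / 30.0, 1 / 5.0, 500)
        ref = np.sin(chi(freqs, 0.0, optics, CtfParams(10000.0, 10000.0))) ** 2
        scores = []
        for delta in np.arange(0.0, 2001.0, 250.0):
            other = np.sin(
                chi(freqs, 0.0, optics, CtfParams(10000.0 + delta, 10000.0 + delta))
            ) ** 2
            scores.append(ncc_score(ref, other))
        # strictly declining until the rings fully decorrelate, and the match
        # never recovers anywhere near the true-defocus score
        assert np.all(np.diff(scores[:5]) < 0)
        assert max(scores[1:]) < 0.9


class TestDefocusSearch1D:
    def test_exact_recovery_noiseless(self, optics):
        prof = _profile_for(optics, 10000.0)
        found = search_defocus_1d(prof, optics, (5000.0, 50000.0), 100.0, 30.0, 5.0)
        assert found == 10000.0

    def test_noise_robustness_one_step(self, optics):
        # white noise at half the signal RMS moves the argmax at most one step
        prof = _profile_for(optics, 12000.0)
        sigma = 0.5 * prof.amplitudes.std()
        for seed in range(3):
            noisy = RadialProfile(
                prof.freqs,
                prof.amplitudes
                + np.random.default_rng(seed).normal(0, sigma, prof.freqs.size),
            )
            found = search_defocus_1d(noisy, optics, (5000.0, 50000.0), 100.0, 30.0, 5.0)
            assert abs(found - 12000.0) <= 100.0

    def test_empty_grid_rejected(self, optics):
        with pytest.raises(ValueError):
            search_defocus_1d(
                _profile_for(optics, 1e4), optics, (5000.0, 4000.0), 100.0, 30.0, 5.0
            )


def _synthetic_spectrum(spec: SyntheticSpec, box=512):
    img = synth_micrograph(spec)
    ps = tile_average_spectrum(img, box, spec.pixel_size)
    return subtract_background_box(ps)


class TestRefine2D:
    def test_init_at_truth_stays(self, optics):
        spec = SyntheticSpec(size=1024, defocus_1=10500, defocus_2=9500,
                             astig_angle_deg=30.0, seed=5)
        ps = _synthetic_spectrum(spec)
        truth = CtfParams(10500.0, 9500.0, 30.0)
        init_score = score_spectrum_2d(ps, optics, truth, 30.0, 5.0)
        refined, score = refine_2d(ps, optics, truth)
        assert score >= init_score
        assert refined.defocus_1 == pytest.approx(10500.0, rel=0.01)
        assert refined.defocus_2 == pytest.approx(9500.0, rel=0.01)

    def test_recovery_from_1d_init(self, optics):
        spec = SyntheticSpec(size=1024, defocus_1=10500, defocus_2=9500,
                             astig_angle_deg=30.0, seed=6)
        ps = _synthetic_spectrum(spec)
        prof = radial_average(ps)
        df0 = search_defocus_1d(prof, optics, (5000.0, 50000.0), 100.0, 30.0, 5.0)
        refined, _ = refine_2d(ps, optics, CtfParams(df0, df0))
        assert refined.defocus_1 == pytest.approx(10500.0, rel=0.01)
        assert refined.defocus_2 == pytest.approx(9500.0, rel=0.01)
        assert abs(refined.astig_angle_deg - 30.0) <= 2.0

    def test_frozen_parameters_untouched(self, optics):
        spec = SyntheticSpec(size=512, defocus_1=10500, defocus_2=9500,
                             astig_angle_deg=30.0, seed=7)
        ps = _synthetic_spectrum(spec, box=256)
        init = CtfParams(10400.0, 9400.0, 10.0)
        refined, _ = refine_2d(ps, optics, init, free_params=("astig_angle_deg",))
        assert refined.defocus_1 == 10400.0
        assert refined.defocus_2 == 9400.0

    def test_unknown_free_parameter_rejected(self, optics):
        ps = PowerSpectrum2D(np.zeros((64, 64)), 1.0)
        with pytest.raises(ValueError):
            refine_2d(ps, optics, CtfParams(1e4, 1e4), free_params=("voltage",))


class TestGoodnessOfFit:
    def _curve(self, optics, observed=None):
        freqs = np.linspace(1 / 30.0, 1 / 5.0, 600)
        ctf = CtfParams(10000.0, 10000.0)
        model = model_profile(freqs, optics, ctf)
        chi_vals = chi(freqs, 0.0, optics, ctf)
        obs = model if observed is None else observed
        return goodness_of_fit_curve(freqs, obs, model, chi_vals)

    def test_model_vs_itself_is_unity(self, optics):
        freqs, curve = self._curve(optics)
        assert np.all(curve > 0.999)

    def test_random_tail_drops_curve(self, optics):
        freqs = np.linspace(1 / 30.0, 1 / 5.0, 600)
        ctf = CtfParams(10000.0, 10000.0)
        model = model_profile(freqs, optics, ctf)
        g0 = 1 / 8.0
        obs = model.copy()
        tail = freqs > g0
        obs[tail] = np.random.default_rng(0).random(tail.sum())
        chi_vals = chi(freqs, 0.0, optics, ctf)
        _, curve = goodness_of_fit_curve(freqs, obs, model, chi_vals)
        res = fit_resolution(freqs, curve, res_high=5.0)
        assert 7.0 <= res <= 9.5

    def test_fit_resolution_never_decayed(self):
        freqs = np.linspace(0.05, 0.2, 100)
        assert fit_resolution(freqs, np.ones(100), res_high=5.0) == 5.0

    def test_fit_resolution_step_drop(self):
        freqs = np.linspace(0.05, 0.3, 251)
        curve = np.where(freqs < 0.2, 1.0, 0.0)
        assert fit_resolution(freqs, curve, res_high=3.0) == pytest.approx(5.0, rel=0.01)

    def test_single_bin_dip_ignored(self):
        freqs = np.linspace(0.05, 0.3, 251)
        curve = np.ones(251)
        curve[100] = 0.0
        assert fit_resolution(freqs, curve, res_high=3.0) == 3.0
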