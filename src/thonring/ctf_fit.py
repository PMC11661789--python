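"""Baseline CTF fitting: exhaustive 1D defocus search, 2D astigmatic
refinement, goodness-of-fit curves and the fit resolution.

Scores are Pearson-type normalized cross-correlations (NCC) between the
background-subtracted amplitude spectrum and the model |sin chi| (thin
specimen) or the thickness-modulated power-spectrum model.  The
goodness-of-fit curve is a sliding-window NCC along the 1D profile; the
window spans a fixed number of model oscillations (measured in units of the
CTF phase chi, where sin^2 chi has period pi), widened 1.5x when the
thickness model is in use so the node regions do not truncate the fit.  The
fit resolution is where that curve first drops below threshold and stays
below it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
from scipy import optimize

from .ctf_model import CtfParams, OpticsParams, chi, ctf_thick, ctf_thin
from .spectrum import PowerSpectrum2D, RadialProfile

__all__ = [
    "FitQuality",
    "ncc_score",
    "search_defocus_1d",
    "refine_2d",
    "goodness_of_fit_curve",
    "fit_resolution",
    "model_profile",
]

BASELINE_GOF_OSCILLATIONS = 3.0
THICKNESS_GOF_FACTOR = 1.5


@dataclass
class FitQuality:
    """Fit diagnostics: overall NCC, windowed NCC curve and fit resolution."""

    score: float
    gof_freqs: np.ndarray
    gof_curve: np.ndarray
    fit_resolution_angstrom: float


def ncc_score(observed, model, mask=None) -> float:
    """Mean-subtracted, unit-normalized cross-correlation of two samples.

    Degenerate (zero-variance) inputs score 0.
    """
    a = np.asarray(observed, dtype=float).ravel()
    b = np.asarray(model, dtype=float).ravel()
    if mask is not None:
        m = np.asarray(mask).ravel()
        a, b = a[m], b[m]
    if a.size == 0:
        return 0.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0.0:
        return 0.0
    return float(np.dot(a, b) / denom)


def model_profile(
    freqs: np.ndarray,
    optics: OpticsParams,
    ctf: CtfParams,
    thick: bool = False,
) -> np.ndarray:
    """1D model evaluated at the mean defocus: |sin chi| or the thick model."""
    mean = CtfParams(ctf.defocus_mean, ctf.defocus_mean, 0.0, thickness=ctf.thickness)
    if thick:
        return ctf_thick(freqs, 0.0, optics, mean)
    return np.abs(ctf_thin(freqs, 0.0, optics, mean))


def search_defocus_1d(
    profile: RadialProfile,
    optics: OpticsParams,
    defocus_range: tuple[float, float],
    step: float,
    res_low: float,
    res_high: float,
) -> float:
    """Exhaustive non-astigmatic defocus search on a 1D profile.

    Scans the grid ``defocus_min..defocus_max`` (step in Angstrom) and returns
    the defocus maximizing the NCC between the profile and |sin chi| over the
    fitting band.  Exact ties resolve to the lowest defocus.
    """
    lo, hi = defocus_range
    grid = np.arange(lo, hi + 0.5 * step, step)
    if grid.size == 0:
        raise ValueError("empty defocus grid")
    band = profile.band_mask(res_low, res_high)
    freqs = profile.freqs[band]
    obs = profile.amplitudes[band]
    best_df, best_score = float(grid[0]), -np.inf
    for df in grid:
        model = np.abs(ctf_thin(freqs, 0.0, optics, CtfParams(df, df)))
        s = ncc_score(obs, model)
        if s > best_score:
            best_df, best_score = float(df), s
    return best_df


def _spectrum_band_mask(ps: PowerSpectrum2D, res_low: float, res_high: float):
    g_mag, g_ang = ps.frequency_grids()
    mask = (g_mag >= 1.0 / res_low) & (g_mag <= 1.0 / res_high)
    return g_mag, g_ang, mask


def score_spectrum_2d(
    ps: PowerSpectrum2D,
    optics: OpticsParams,
    ctf: CtfParams,
    res_low: float,
    res_high: float,
    thick: bool = False,
) -> float:
    """NCC between a 2D spectrum and the astigmatic model over the band annulus."""
    g_mag, g_ang, mask = _spectrum_band_mask(ps, res_low, res_high)
    if thick:
        model = ctf_thick(g_mag[mask], g_ang[mask], optics, ctf)
    else:
        model = np.abs(ctf_thin(g_mag[mask], g_ang[mask], optics, ctf))
    return ncc_score(ps.amplitudes[mask], model)


_PARAM_ORDER = ("defocus_1", "defocus_2", "astig_angle_deg", "thickness")
# optimizer step scale per parameter (Angstrom / degrees)
_PARAM_SCALE = {"defocus_1": 100.0, "defocus_2": 100.0, "astig_angle_deg": 5.0,
                "thickness": 100.0}


def refine_2d(
    ps: PowerSpectrum2D,
    optics: OpticsParams,
    init: CtfParams,
    free_params: Iterable[str] = ("defocus_1", "defocus_2", "astig_angle_deg"),
    res_low: float = 30.0,
    res_high: float = 5.0,
    thick: bool = False,
) -> tuple[CtfParams, float]:
    """Local refinement of the astigmatic (optionally thick) model on a 2D spectrum.

    Maximizes the NCC with respect to the requested free parameters from the
    given initialization (Nelder-Mead simplex); frozen parameters are passed
    through untouched.  The returned score never falls below the score of the
    initialization, and the returned parameters are canonicalized
    (defocus_1 >= defocus_2).
    """
    free = [p for p in _PARAM_ORDER if p in set(free_params)]
    unknown = set(free_params) - set(_PARAM_ORDER)
    if unknown:
        raise ValueError(f"unknown free parameters: {sorted(unknown)}")
    g_mag, g_ang, mask = _spectrum_band_mask(ps, res_low, res_high)
    gm, ga = g_mag[mask], g_ang[mask]
    obs = ps.amplitudes[mask]

    def build(x) -> CtfParams:
        kwargs = {p: float(v) for p, v in zip(free, x)}
        return replace(init, **kwargs)

    def negscore(x) -> float:
        params = build(x)
        if thick:
            if params.thickness is None or params.thickness <= 0:
                return 1.0
            model = ctf_thick(gm, ga, optics, params)
        else:
            model = np.abs(ctf_thin(gm, ga, optics, params))
        return -ncc_score(obs, model)

    x0 = np.array([getattr(init, p) for p in free], dtype=float)
    init_score = -negscore(x0)
    if not free:
        return init.canonicalized(), init_score
    steps = np.array([_PARAM_SCALE[p] for p in free])
    simplex = np.vstack([x0] + [x0 + np.eye(len(free))[i] * steps[i]
                                for i in range(len(free))])
    res = optimize.minimize(
        negscore, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": 1.0, "fatol": 1e-6,
                 "maxiter": 400 * len(free)},
    )
    if -res.fun >= init_score:
        best, score = build(res.x), float(-res.fun)
    else:  # monotone-score contract: never worse than the initialization
        best, score = init, init_score
    return best.canonicalized(), score


def goodness_of_fit_curve(
    freqs: np.ndarray,
    observed: np.ndarray,
    model: np.ndarray,
    chi_values: np.ndarray,
    window_oscillations: float = BASELINE_GOF_OSCILLATIONS,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window NCC between observed and model profiles.

    The window centered at sample ``i`` contains all samples whose CTF phase
    differs from ``chi_values[i]`` by at most ``window_oscillations * pi / 2``
    — i.e. it spans a fixed number of model oscillations regardless of how
    the ring spacing compresses with frequency.  Edge windows are truncated.
    Returns ``(freqs, curve)``.
    """
    freqs = np.asarray(freqs, float)
    observed = np.asarray(observed, float)
    model = np.asarray(model, float)
    chi_values = np.asarray(chi_values, float)
    half = 0.5 * window_oscillations * np.pi
    n = len(freqs)
    curve = np.empty(n)
    lo = np.searchsorted(chi_values, chi_values - half, side="left")
    hi = np.searchsorted(chi_values, chi_values + half, side="right")
    for i in range(n):
        a, b = lo[i], max(hi[i], lo[i] + 3)
        curve[i] = ncc_score(observed[a:b], model[a:b])
    return freqs, curve


def fit_resolution(
    freqs: np.ndarray,
    curve: np.ndarray,
    threshold: float = 0.5,
    res_high: float = 5.0,
    persistence: int = 2,
) -> float:
    """Resolution (Angstrom) where the goodness-of-fit is lost.

    The first frequency at which the curve drops below ``threshold`` and
    stays below for at least ``persistence`` consecutive samples; a
    single-sample dip does not terminate the fit.  If the curve never decays,
    returns ``res_high`` (the band edge).
    """
    below = np.asarray(curve) < threshold
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run >= persistence:
            start = i - persistence + 1
            f = freqs[start]
            if f > 0:
                return float(1.0 / f)
    return float(res_high)


def quality_from_profile(
    profile: RadialProfile,
    optics: OpticsParams,
    ctf: CtfParams,
    res_low: float,
    res_high: float,
    thick: bool = False,
) -> FitQuality:
    """Assemble the FitQuality diagnostics for a 1D profile and a model."""
    band = profile.band_mask(res_low, res_high)
    freqs = profile.freqs[band]
    obs = profile.amplitudes[band]
    model = model_profile(freqs, optics, ctf, thick=thick)
    mean = CtfParams(ctf.defocus_mean, ctf.defocus_mean, 0.0)
    chi_vals = chi(freqs, 0.0, optics, mean)
    window = BASELINE_GOF_OSCILLATIONS * (THICKNESS_GOF_FACTOR if thick else 1.0)
    _, curve = goodness_of_fit_curve(freqs, obs, model, chi_vals, window)
    res = fit_resolution(freqs, curve, res_high=res_high)
    return FitQuality(ncc_score(obs, model), freqs, curve, res)
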