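"""Sample-thickness estimation from the sinc modulation of Thon rings.

A slab of thickness ``t`` multiplies the Thon-ring oscillation by
``sinc(pi * lambda * g^2 * t)``: the ring amplitude decays with frequency,
vanishes at the node ``g = 1/sqrt(lambda t)`` and the rings re-appear
phase-inverted beyond it.  The estimator proceeds in stages:

1. initialize ``t`` from the goodness-of-fit resolution of the thin-model
   fit, interpreting the frequency where the fit dies as the first node;
2. optionally a brute-force 1D search over (t, defocus) against the
   equiphase-averaged profile scaled to oscillate around 0.5 (t in
   50-400 nm / 10 nm steps, defocus within +-200 nm of the prior fit);
3. optionally a simplex 2D refinement of (t, defocus_1, defocus_2,
   astigmatism angle) against the 2D spectrum;
4. re-derive the goodness-of-fit curve with a 1.5x wider window so the node
   region does not truncate the fit resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ctf_model import (
    CtfParams,
    OpticsParams,
    ctf_thick,
    thickness_from_node,
)
from .ctf_fit import FitQuality, ncc_score, quality_from_profile, refine_2d
from .spectrum import PowerSpectrum2D, RadialProfile

__all__ = [
    "ThicknessSearchConfig",
    "init_thickness",
    "brute_force_1d",
    "refine_thickness_2d",
    "estimate_thickness",
]

FALLBACK_THICKNESS = 1500.0  # Angstrom (150 nm), used when the GoF never decays


@dataclass(frozen=True)
class ThicknessSearchConfig:
    """Grids and band of the thickness search (Angstrom).

    Defaults: t in 500..4000 A (50-400 nm) in 100 A steps, defocus within
    +-2000 A of the prior fit in 100 A steps, scored over the 10-3 A band.
    """

    t_min: float = 500.0
    t_max: float = 4000.0
    t_step: float = 100.0
    defocus_window: float = 2000.0
    defocus_step: float = 100.0
    res_low: float = 10.0
    res_high: float = 3.0


def init_thickness(gof_resolution: float, wavelength: float, res_high: float):
    """Thickness implied by reading the goodness-of-fit resolution as the first node.

    Returns ``(t, fallback)``: when the thin-model fit never decayed
    (``gof_resolution`` at the band edge ``res_high``) there is no node to
    read and a mid-range default of 150 nm is returned with ``fallback=True``.
    """
    if gof_resolution <= res_high or np.isclose(gof_resolution, res_high, rtol=1e-3):
        return FALLBACK_THICKNESS, True
    return thickness_from_node(1.0 / gof_resolution, wavelength), False


def brute_force_1d(
    epa_profile: RadialProfile,
    optics: OpticsParams,
    defocus_init: float,
    config: ThicknessSearchConfig = ThicknessSearchConfig(),
) -> tuple[float, float]:
    """Exhaustive (t, defocus) search against the 0.5-centered EPA profile.

    Maximizes the NCC between the profile and the thick-specimen model over
    the configured grids; returns ``(t, defocus)``.  Ties resolve to the
    lowest (t, defocus) pair.
    """
    band = epa_profile.band_mask(config.res_low, config.res_high)
    freqs = epa_profile.freqs[band]
    obs = epa_profile.amplitudes[band]
    if freqs.size == 0:
        raise ValueError("empty thickness fitting band")
    t_grid = np.arange(config.t_min, config.t_max + 0.5 * config.t_step, config.t_step)
    df_grid = np.arange(
        defocus_init - config.defocus_window,
        defocus_init + config.defocus_window + 0.5 * config.defocus_step,
        config.defocus_step,
    )
    best = (float(t_grid[0]), float(df_grid[0]))
    best_score = -np.inf
    for t in t_grid:
        for df in df_grid:
            model = ctf_thick(freqs, 0.0, optics, CtfParams(df, df, thickness=t))
            s = ncc_score(obs, model)
            if s > best_score:
                best, best_score = (float(t), float(df)), s
    return best


def refine_thickness_2d(
    ps: PowerSpectrum2D,
    optics: OpticsParams,
    init: CtfParams,
    config: ThicknessSearchConfig = ThicknessSearchConfig(),
) -> tuple[CtfParams, float]:
    """Simplex refinement of (t, defocus_1, defocus_2, astigmatism angle)
    against the 2D spectrum with the thick-specimen model."""
    return refine_2d(
        ps, optics, init,
        free_params=("defocus_1", "defocus_2", "astig_angle_deg", "thickness"),
        res_low=config.res_low, res_high=config.res_high, thick=True,
    )


def estimate_thickness(
    ps: PowerSpectrum2D,
    epa_scaled: RadialProfile,
    optics: OpticsParams,
    baseline: CtfParams,
    baseline_quality: FitQuality,
    brute_force: bool = True,
    refine: bool = True,
    config: ThicknessSearchConfig = ThicknessSearchConfig(),
) -> tuple[CtfParams, FitQuality]:
    """Full thickness stage on top of a completed thin-model fit.

    ``ps`` is the background-subtracted 2D spectrum the baseline was fitted
    to (the tilt-corrected one when tilt estimation ran first) and
    ``epa_scaled`` the equiphase-averaged profile scaled about 0.5.  Returns
    the parameters with thickness set, plus the goodness-of-fit recomputed
    with the widened window.
    """
    t0, _fallback = init_thickness(
        baseline_quality.fit_resolution_angstrom, optics.wavelength, config.res_high
    )
    params = replace(baseline, thickness=float(np.clip(t0, config.t_min, config.t_max)))
    if brute_force:
        t, df = brute_force_1d(epa_scaled, optics, baseline.defocus_mean, config)
        astig = baseline.defocus_1 - baseline.defocus_2
        params = replace(
            baseline,
            defocus_1=df + 0.5 * astig,
            defocus_2=df - 0.5 * astig,
            thickness=t,
        )
    if refine:
        params, _ = refine_thickness_2d(ps, optics, params, config)
    quality = quality_from_profile(
        epa_scaled, optics, params, config.res_low, config.res_high, thick=True
    )
    return params.canonicalized(), quality
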