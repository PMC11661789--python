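"""End-to-end CTF estimation: spectrum -> defocus search -> refinement ->
optional tilt and thickness stages.

The stage order follows the estimator's logic: when tilt estimation is
requested the micrograph is first Fourier-cropped to the fitting resolution
and square-cropped, an initial defocus comes from a highly binned (128-px)
spectrum, the tilt plane is searched on local tile spectra, and a
tilt-corrected average spectrum replaces the plain tile average for all
subsequent fitting.  Thickness estimation, when requested, runs last on the
(possibly tilt-corrected) spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .ctf_fit import (
    FitQuality,
    quality_from_profile,
    refine_2d,
    search_defocus_1d,
)
from .ctf_model import CtfParams, OpticsParams
from .io import Micrograph, RunConfig
from .spectrum import (
    PowerSpectrum2D,
    RadialProfile,
    crop_square,
    equiphase_average,
    fourier_crop,
    scale_profile_for_thickness_display,
    subtract_background_box,
    tile_average_spectrum,
)
from .thickness import ThicknessSearchConfig, estimate_thickness
from .tilt import TiltResult, build_tile_set, coarse_tilt_search, refine_tilt, tilt_corrected_spectrum

__all__ = ["CtfEstimate", "estimate_ctf"]

logger = logging.getLogger("thonring")


@dataclass
class CtfEstimate:
    """Everything a run produces: parameters, diagnostics and the spectrum."""

    params: CtfParams
    quality: FitQuality
    spectrum: PowerSpectrum2D
    profile: RadialProfile
    tilt: TiltResult | None = None


def _baseline_fit(
    ps: PowerSpectrum2D,
    optics: OpticsParams,
    config: RunConfig,
    init_defocus: float | None = None,
) -> tuple[CtfParams, FitQuality, RadialProfile]:
    """1D exhaustive search (unless initialized) + 2D astigmatic refinement."""
    from .spectrum import radial_average

    if init_defocus is None:
        profile = radial_average(ps)
        init_defocus = search_defocus_1d(
            profile, optics, (config.defocus_min, config.defocus_max),
            config.defocus_step, config.res_low, config.res_high,
        )
    params = CtfParams(init_defocus, init_defocus, 0.0)
    params, _ = refine_2d(
        ps, optics, params,
        free_params=("defocus_1", "defocus_2", "astig_angle_deg"),
        res_low=config.res_low, res_high=config.res_high,
    )
    epa = equiphase_average(ps, params, optics)
    quality = quality_from_profile(epa, optics, params, config.res_low, config.res_high)
    return params, quality, epa


def estimate_ctf(micrograph: Micrograph, config: RunConfig | None = None) -> CtfEstimate:
    """Estimate defocus/astigmatism and optionally tilt and thickness."""
    config = config or RunConfig()
    config.validate(micrograph.pixel_size)
    optics = micrograph.optics
    px = micrograph.pixel_size
    image = crop_square(micrograph.pixels)
    logger.info(
        "estimating CTF: %dx%d px at %.3f A/px, band %.1f-%.1f A, defocus "
        "%.0f-%.0f A step %.0f",
        *image.shape, px, config.res_low, config.res_high,
        config.defocus_min, config.defocus_max, config.defocus_step,
    )

    tilt_result: TiltResult | None = None
    if config.estimate_tilt:
        binned, binned_px = fourier_crop(image, px, config.res_high)
        binned = crop_square(binned)
        ps128 = subtract_background_box(
            tile_average_spectrum(binned, 128, binned_px)
        )
        init_params, _, _ = _baseline_fit(ps128, optics, config)
        tiles = build_tile_set(binned, binned_px, config.res_low, config.res_high)
        coarse = coarse_tilt_search(tiles, optics, init_params.defocus_mean)
        tilt_result = refine_tilt(tiles, optics, coarse)
        logger.info(
            "tilt estimate: theta=%.2f deg, phi=%.2f deg, defocus=%.0f A",
            tilt_result.theta_deg, tilt_result.phi_deg, tilt_result.defocus_avg,
        )
        out_box = min(config.box_size, min(image.shape))
        ps = tilt_corrected_spectrum(image, px, tilt_result, out_box=out_box)
        ps = subtract_background_box(ps)
        params, quality, epa = _baseline_fit(
            ps, optics, config, init_defocus=tilt_result.defocus_avg
        )
    else:
        out_box = min(config.box_size, min(image.shape))
        ps = subtract_background_box(tile_average_spectrum(image, out_box, px))
        params, quality, epa = _baseline_fit(ps, optics, config)

    profile = epa
    if config.estimate_thickness:
        tconf = ThicknessSearchConfig(
            res_low=config.thickness_res_low, res_high=config.thickness_res_high
        )
        epa_thick = equiphase_average(ps, params, optics)
        epa_scaled = scale_profile_for_thickness_display(epa_thick)
        params, quality = estimate_thickness(
            ps, epa_scaled, optics, params, quality,
            brute_force=config.brute_force_1d, refine=config.refine_2d,
            config=tconf,
        )
        profile = epa_scaled
        logger.info("thickness estimate: %.0f A", params.thickness)

    if tilt_result is not None:
        params.tilt_angle_deg = tilt_result.theta_deg
        params.tilt_axis_deg = tilt_result.phi_deg
    return CtfEstimate(params, quality, ps, profile, tilt_result)
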