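"""Micrograph container, run configuration and CTFFIND-style text outputs."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ctf_model import CtfParams, OpticsParams
from .ctf_fit import FitQuality, model_profile
from .mrc import read_mrc_array, write_mrc_array
from .spectrum import PowerSpectrum2D, RadialProfile

__all__ = ["Micrograph", "RunConfig", "read_mrc", "write_mrc", "write_results"]

logger = logging.getLogger("thonring")

MIN_DIMENSION = 128


@dataclass
class Micrograph:
    """A single 2D image with its pixel size (Angstrom) and optics."""

    pixels: np.ndarray
    pixel_size: float
    optics: OpticsParams = field(default_factory=OpticsParams)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pixels.ndim != 2 or min(self.pixels.shape) < MIN_DIMENSION:
            raise ValueError(
                f"micrograph must be 2D with both dimensions >= {MIN_DIMENSION}, "
                f"got {self.pixels.shape}"
            )


@dataclass
class RunConfig:
    """Estimation settings (CTFFIND conventions: Angstrom everywhere)."""

    box_size: int = 512
    res_low: float = 30.0
    res_high: float = 5.0
    defocus_min: float = 5000.0
    defocus_max: float = 50000.0
    defocus_step: float = 100.0
    estimate_tilt: bool = False
    estimate_thickness: bool = False
    brute_force_1d: bool = True
    refine_2d: bool = True
    thickness_res_low: float = 10.0
    thickness_res_high: float = 3.0

    def validate(self, pixel_size: float) -> None:
        if not (self.res_low > self.res_high > 2.0 * pixel_size):
            raise ValueError(
                f"need res_low > res_high > 2*pixel_size, got "
                f"{self.res_low} / {self.res_high} at {pixel_size} A/px"
            )
        if self.defocus_min > self.defocus_max:
            raise ValueError("defocus_min must not exceed defocus_max")
        if self.defocus_step <= 0:
            raise ValueError("defocus_step must be positive")


def read_mrc(
    path,
    optics: OpticsParams | None = None,
    pixel_size: float | None = None,
    section: int | None = None,
) -> Micrograph:
    """Read an MRC2014 file into a Micrograph.

    The pixel size comes from the header cell unless overridden.
    """
    data, header_px = read_mrc_array(path, section=section)
    px = pixel_size if pixel_size is not None else header_px
    if px <= 0:
        raise ValueError(f"{path}: header carries no pixel size; pass pixel_size")
    return Micrograph(data, px, optics or OpticsParams())


def write_mrc(path, micrograph: Micrograph) -> None:
    write_mrc_array(path, micrograph.pixels, micrograph.pixel_size)


def _summary_lines(ctf: CtfParams, quality: FitQuality, optics: OpticsParams,
                   config: RunConfig) -> list[str]:
    lines = [
        "# thonring CTF estimate",
        f"voltage_kv\t{optics.voltage_kv:.1f}",
        f"cs_mm\t{optics.cs_mm:.2f}",
        f"amplitude_contrast\t{optics.amplitude_contrast:.3f}",
        f"phase_shift_rad\t{optics.phase_shift_rad:.4f}",
        f"defocus_1_A\t{ctf.defocus_1:.1f}",
        f"defocus_2_A\t{ctf.defocus_2:.1f}",
        f"astig_angle_deg\t{ctf.astig_angle_deg:.2f}",
        f"score\t{quality.score:.4f}",
        f"fit_resolution_A\t{quality.fit_resolution_angstrom:.2f}",
    ]
    if ctf.thickness is not None:
        lines.append(f"thickness_A\t{ctf.thickness:.1f}")
    if ctf.tilt_angle_deg is not None:
        lines.append(f"tilt_angle_deg\t{ctf.tilt_angle_deg:.2f}")
        lines.append(f"tilt_axis_deg\t{ctf.tilt_axis_deg:.2f}")
    return lines


def write_results(
    ctf: CtfParams,
    quality: FitQuality,
    optics: OpticsParams,
    config: RunConfig,
    profile: RadialProfile,
    spectrum: PowerSpectrum2D,
    outdir,
    prefix: str = "ctf",
) -> dict[str, Path]:
    """Write the summary text, the 1D profile table and the diagnostic spectrum.

    The profile table has ``box_size // 2`` rows (one per full Fourier pixel
    up to Nyquist) with columns: spatial frequency (1/A), EPA amplitude,
    fitted model, windowed goodness-of-fit CC.  The diagnostic MRC shows the
    observed spectrum with the fitted model rendered in the left half.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    summary = outdir / f"{prefix}_summary.txt"
    summary.write_text("\n".join(_summary_lines(ctf, quality, optics, config)) + "\n")
    paths["summary"] = summary

    n_rows = spectrum.box_size // 2
    freqs = np.arange(n_rows) / (spectrum.box_size * spectrum.pixel_size)
    amps = np.interp(freqs, profile.freqs, profile.amplitudes)
    thick = ctf.thickness is not None
    model = model_profile(freqs, optics, ctf, thick=thick)
    gof = np.interp(freqs, quality.gof_freqs, quality.gof_curve, left=1.0, right=0.0)
    table = pd.DataFrame(
        {
            "frequency_1_per_A": freqs,
            "epa_amplitude": amps,
            "model": model,
            "goodness_of_fit": gof,
        }
    )
    profile_path = outdir / f"{prefix}_profile.tsv"
    table.to_csv(profile_path, sep="\t", index=False, float_format="%.6f")
    paths["profile"] = profile_path

    diag = _diagnostic_image(spectrum, optics, ctf)
    diag_path = outdir / f"{prefix}_spectrum.mrc"
    write_mrc_array(diag_path, diag, spectrum.pixel_size)
    paths["spectrum"] = diag_path
    return paths


def _diagnostic_image(ps: PowerSpectrum2D, optics: OpticsParams, ctf: CtfParams):
    from .ctf_model import ctf_thick, ctf_thin

    g_mag, g_ang = ps.frequency_grids()
    if ctf.thickness is not None:
        model = ctf_thick(g_mag, g_ang, optics, ctf)
    else:
        model = np.abs(ctf_thin(g_mag, g_ang, optics, ctf))
    obs = ps.amplitudes
    lo, hi = np.percentile(obs, [1, 99])
    obs = np.clip((obs - lo) / max(hi - lo, 1e-12), 0.0, 1.0)
    out = obs.copy()
    half = ps.box_size // 2
    out[:, :half] = model[:, :half]
    return out
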