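"""Power-spectrum preparation for Thon-ring fitting.

A micrograph is turned into a background-subtracted amplitude spectrum in
stages: optional Fourier-crop binning to the fitting resolution, square
cropping, tile-averaged amplitude spectra (sqrt of the mean tile power
spectrum), box-convolution background removal, and finally a 1D profile —
either a plain radial average or an equiphase average (EPA) which removes
astigmatism blurring by binning pixels on contours of equal CTF phase rather
than equal |g|.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .ctf_model import (
    CtfParams,
    OpticsParams,
    amplitude_contrast_phase,
    chi,
)

__all__ = [
    "PowerSpectrum2D",
    "RadialProfile",
    "fourier_crop",
    "crop_square",
    "tile_average_spectrum",
    "subtract_background_box",
    "radial_average",
    "equiphase_average",
    "scale_profile_for_thickness_display",
]


@dataclass
class PowerSpectrum2D:
    """Origin-centered square amplitude spectrum.

    ``amplitudes[i, j]`` corresponds to the spatial frequency whose magnitude
    is ``dist((i, j), center) / (box_size * pixel_size)`` with
    ``center = box_size // 2``.
    """

    amplitudes: np.ndarray
    pixel_size: float
    background_subtracted: bool = False

    @property
    def box_size(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def nyquist(self) -> float:
        return 0.5 / self.pixel_size

    def frequency_grids(self):
        """Return (g_mag, g_angle) arrays for every spectrum pixel."""
        n = self.box_size
        c = n // 2
        idx = (np.arange(n) - c) / (n * self.pixel_size)
        gy, gx = np.meshgrid(idx, idx, indexing="ij")
        return np.hypot(gx, gy), np.arctan2(gy, gx)


@dataclass
class RadialProfile:
    """1D spectrum profile on an increasing frequency grid (1/Angstrom)."""

    freqs: np.ndarray
    amplitudes: np.ndarray
    kind: str = "radial"  # "radial" | "equiphase"

    def band_mask(self, res_low: float, res_high: float) -> np.ndarray:
        """Boolean mask selecting the fitting band res_low..res_high (Angstrom)."""
        return (self.freqs >= 1.0 / res_low) & (self.freqs <= 1.0 / res_high)


def _even(n: int) -> int:
    return n - (n % 2)


def crop_square(image: np.ndarray) -> np.ndarray:
    """Central square crop with an even side length."""
    h, w = image.shape
    side = _even(min(h, w))
    r0 = (h - side) // 2
    c0 = (w - side) // 2
    return image[r0 : r0 + side, c0 : c0 + side]


def fourier_crop(image: np.ndarray, pixel_size: float, target_resolution: float):
    """Bin an image by Fourier cropping so its Nyquist matches ``target_resolution``.

    Returns ``(binned_image, new_pixel_size)``.  The image mean is preserved
    (the DC term is rescaled with the array size).  If the target is finer
    than the current Nyquist the image is returned unchanged.
    """
    if target_resolution < 2.0 * pixel_size:
        return image, pixel_size
    h, w = image.shape
    scale = 2.0 * pixel_size / target_resolution
    nh, nw = _even(max(2, round(h * scale))), _even(max(2, round(w * scale)))
    if nh >= h and nw >= w:
        return image, pixel_size
    ft = np.fft.fftshift(np.fft.fft2(image))
    r0, c0 = (h - nh) // 2, (w - nw) // 2
    ft = ft[r0 : r0 + nh, c0 : c0 + nw]
    out = np.fft.ifft2(np.fft.ifftshift(ft)).real * (nh * nw) / (h * w)
    # pixel size grows by the inverse of the retained Fourier fraction
    return out, pixel_size * h / nh


def tile_average_spectrum(
    image: np.ndarray,
    tile_size: int,
    pixel_size: float,
    overlap: float = 0.5,
) -> PowerSpectrum2D:
    """Average amplitude spectrum over a regular grid of square tiles.

    Tiles of ``tile_size`` pixels are laid out with the given fractional
    overlap (0.5 by default); the amplitude spectrum is the square root of
    the mean tile power spectrum, fftshifted so the origin sits at
    ``tile_size // 2``.
    """
    h, w = image.shape
    if h < tile_size or w < tile_size:
        raise ValueError(f"image {image.shape} smaller than tile_size {tile_size}")
    stride = max(1, int(round(tile_size * (1.0 - overlap))))
    power = np.zeros((tile_size, tile_size))
    n = 0
    for y0 in _tile_starts(h, tile_size, stride):
        for x0 in _tile_starts(w, tile_size, stride):
            tile = image[y0 : y0 + tile_size, x0 : x0 + tile_size]
            tile = tile - tile.mean()
            ft = np.fft.fft2(tile)
            power += np.abs(ft) ** 2
            n += 1
    power /= n * tile_size * tile_size
    amp = np.sqrt(np.fft.fftshift(power))
    return PowerSpectrum2D(amp, pixel_size)


def _tile_starts(extent: int, tile: int, stride: int):
    starts = list(range(0, extent - tile + 1, stride))
    if starts and starts[-1] != extent - tile:
        starts.append(extent - tile)
    return starts


def subtract_background_box(ps: PowerSpectrum2D, box_radius: int | None = None) -> PowerSpectrum2D:
    """Remove the smooth background with a box (boxcar) convolution.

    The background is the spectrum smoothed with a square box of half-width
    ``box_radius`` (default: box_size // 16, i.e. a box of box_size/8);
    subtracting it leaves the Thon-ring oscillation centered on zero.
    """
    if box_radius is None:
        box_radius = max(1, ps.box_size // 16)
    if box_radius < 1:
        raise ValueError("box_radius must be >= 1")
    size = 2 * box_radius + 1
    background = ndimage.uniform_filter(ps.amplitudes, size=size, mode="nearest")
    return replace(ps, amplitudes=ps.amplitudes - background, background_subtracted=True)


def _bin_profile(values: np.ndarray, g_equiv: np.ndarray, ps: PowerSpectrum2D, kind: str):
    """Bin spectrum pixels into a uniform frequency grid (0.5 Fourier-pixel bins)."""
    df = 0.5 / (ps.box_size * ps.pixel_size)
    nbins = int(np.floor(ps.nyquist / df)) + 1
    idx = np.round(g_equiv / df).astype(int)
    keep = (idx >= 0) & (idx < nbins)
    sums = np.bincount(idx[keep], weights=values[keep], minlength=nbins)
    counts = np.bincount(idx[keep], minlength=nbins)
    freqs = np.arange(nbins) * df
    amps = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # fill empty bins (possible at the very lowest frequencies) by interpolation
    if np.any(counts == 0) and np.any(counts > 0):
        filled = counts > 0
        amps = np.interp(freqs, freqs[filled], amps[filled])
    return RadialProfile(freqs, amps, kind=kind)


def radial_average(ps: PowerSpectrum2D) -> RadialProfile:
    """Plain rotational average of the spectrum."""
    g_mag, _ = ps.frequency_grids()
    return _bin_profile(ps.amplitudes.ravel(), g_mag.ravel(), ps, "radial")


def equiphase_average(
    ps: PowerSpectrum2D,
    ctf: CtfParams | None,
    optics: OpticsParams,
) -> RadialProfile:
    """Astigmatism-corrected 1D profile by equiphase averaging (EPA).

    Each spectrum pixel is assigned the frequency ``g'`` at which a
    non-astigmatic CTF at the mean defocus reaches the same phase ``chi`` as
    the astigmatic model does at that pixel, then binned by ``g'``.  With a
    quadratic-in-g^2 phase the inversion is closed-form; the spherical
    aberration branch picks the root on the rising flank of chi.  Without a
    current fit the plain radial average is returned.
    """
    if ctf is None:
        return radial_average(ps)
    g_mag, g_ang = ps.frequency_grids()
    phase = chi(g_mag, g_ang, optics, ctf) - (
        optics.phase_shift_rad + amplitude_contrast_phase(optics.amplitude_contrast)
    )
    phase = np.maximum(phase, 0.0)
    lam = optics.wavelength
    df = ctf.defocus_mean
    cs = optics.cs_angstrom
    if cs == 0.0 or df <= 0.0:
        u = phase / (np.pi * lam * max(df, 1e-12))
    else:
        # (pi/2) lam^3 Cs u^2 - pi lam df u + phase = 0, u = g'^2 (smaller root)
        a = 0.5 * np.pi * lam**3 * cs
        b = np.pi * lam * df
        disc = np.maximum(b * b - 4.0 * a * phase, 0.0)
        u = (b - np.sqrt(disc)) / (2.0 * a)
    g_equiv = np.sqrt(np.maximum(u, 0.0))
    return _bin_profile(ps.amplitudes.ravel(), g_equiv.ravel(), ps, "equiphase")


def scale_profile_for_thickness_display(
    profile: RadialProfile, window: int | None = None
) -> RadialProfile:
    """Map a background-subtracted profile to oscillate around 0.5 in [0, 1].

    The local min/max envelope (computed over ``window`` bins, default 1/20
    of the profile) is mapped so troughs approach 0 and crests approach 1,
    symmetric about 0.5 — the display frame of the thickness-modulated model,
    in contrast with scaling minima to 0.  The envelope width is floored at a
    fraction of its median so near-node regions (vanishing oscillation) stay
    close to 0.5 instead of amplifying noise.
    """
    amps = profile.amplitudes
    n = len(amps)
    if window is None:
        window = max(5, n // 20)
    upper = ndimage.maximum_filter1d(amps, size=window, mode="nearest")
    lower = ndimage.minimum_filter1d(amps, size=window, mode="nearest")
    sigma = window / 3.0
    upper = ndimage.gaussian_filter1d(upper, sigma, mode="nearest")
    lower = ndimage.gaussian_filter1d(lower, sigma, mode="nearest")
    width = upper - lower
    ref = np.median(width[width > 0]) if np.any(width > 0) else 0.0
    if ref <= 0:
        return RadialProfile(profile.freqs, np.full(n, 0.5), kind=profile.kind)
    width = np.maximum(width, 0.1 * ref)
    center = 0.5 * (upper + lower)
    scaled = 0.5 + (amps - center) / width
    return RadialProfile(profile.freqs, np.clip(scaled, 0.0, 1.0), kind=profile.kind)
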