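"""Specimen-tilt estimation from locally fitted Thon-ring patterns.

The defocus across a tilted specimen varies as a tilted plane: a point at
signed perpendicular distance ``d`` (Angstrom) from the tilt axis through the
image center sees ``defocus_avg + d * tan(theta)``.  The tilt axis direction
``phi`` is measured counterclockwise from the +x axis in [0, 360); the tilt
angle ``theta`` lies in [0, 90].  (theta, phi) and (theta, phi + 180) describe
the same plane with an inverted gradient, so the sign of the recovered phi
disambiguates which side of the axis is further from focus (d > 0 is further,
i.e. larger defocus).

The search scores each candidate plane by the mean NCC between the radial
profile of each 128-pixel tile spectrum and a non-astigmatic thin-specimen
model at the tile's predicted local defocus: a coarse exhaustive scan in 10
(axis) x 5 (angle) degree steps, then simplex refinement of (theta, phi,
defocus_avg).  Finally an average power spectrum is assembled from larger
tiles whose spectra are radially magnified by m = sqrt(df_local / df_avg) so
every tile's rings land where the average-defocus rings sit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .ctf_model import OpticsParams
from .spectrum import (
    PowerSpectrum2D,
    radial_average,
    subtract_background_box,
    tile_average_spectrum,
    _tile_starts,
)
__all__ = [
    "TileSet",
    "TiltResult",
    "local_defocus",
    "build_tile_set",
    "score_tilt",
    "coarse_tilt_search",
    "refine_tilt",
    "tilt_corrected_spectrum",
]

TILE_SIZE = 128


@dataclass
class TiltResult:
    """Estimated tilt plane: angle/axis in degrees, average defocus in Angstrom."""

    theta_deg: float
    phi_deg: float
    defocus_avg: float
    score: float

    def canonicalized(self) -> "TiltResult":
        theta, phi = self.theta_deg, self.phi_deg
        if theta < 0:
            theta, phi = -theta, phi + 180.0
        return TiltResult(theta, phi % 360.0, self.defocus_avg, self.score)


@dataclass
class TileSet:
    """Grid of local tile spectra reduced to radial profiles for tilt scoring.

    ``centers`` are (x, y) pixel offsets of each tile center from the image
    center; ``profiles`` holds one background-subtracted radial profile per
    tile on the common frequency grid ``freqs`` (restricted to the fit band).
    """

    centers: np.ndarray  # (n_tiles, 2), pixels relative to image center
    profiles: np.ndarray  # (n_tiles, n_freq)
    freqs: np.ndarray  # (n_freq,), 1/Angstrom
    pixel_size: float
    tile_size: int = TILE_SIZE


def local_defocus(defocus_avg, theta_deg, phi_deg, x, y, pixel_size):
    """Defocus of the plane at pixel offset (x, y) from the image center.

    d = (-x sin(phi) + y cos(phi)) * pixel_size  is the signed perpendicular
    distance from the tilt axis (Angstrom); the d > 0 side is further from
    focus.
    """
    phi = np.deg2rad(phi_deg)
    d = (-np.asarray(x) * np.sin(phi) + np.asarray(y) * np.cos(phi)) * pixel_size
    return defocus_avg + d * np.tan(np.deg2rad(theta_deg))


def build_tile_set(
    image: np.ndarray,
    pixel_size: float,
    res_low: float,
    res_high: float,
    tile_size: int = TILE_SIZE,
    overlap: float = 0.5,
) -> TileSet:
    """Cut a square image into a regular grid of tiles and spectra.

    Each tile's amplitude spectrum is background-subtracted and reduced to a
    radial profile over the fitting band.
    """
    h, w = image.shape
    stride = max(1, int(round(tile_size * (1.0 - overlap))))
    centers, profiles = [], []
    freqs = None
    cy, cx = h / 2.0, w / 2.0
    for y0 in _tile_starts(h, tile_size, stride):
        for x0 in _tile_starts(w, tile_size, stride):
            tile = image[y0 : y0 + tile_size, x0 : x0 + tile_size]
            ps = tile_average_spectrum(tile, tile_size, pixel_size, overlap=0.0)
            ps = subtract_background_box(ps)
            prof = radial_average(ps)
            band = prof.band_mask(res_low, res_high)
            if freqs is None:
                freqs = prof.freqs[band]
            profiles.append(prof.amplitudes[band])
            centers.append((x0 + tile_size / 2.0 - cx, y0 + tile_size / 2.0 - cy))
    return TileSet(np.asarray(centers), np.asarray(profiles), freqs, pixel_size,
                   tile_size)


def _model_matrix(freqs, defoci, optics: OpticsParams):
    """|sin chi| model rows for a vector of (non-astigmatic) defoci."""
    lam = optics.wavelength
    g2 = freqs[None, :] ** 2
    from .ctf_model import amplitude_contrast_phase

    phase = (
        np.pi * lam * g2 * (defoci[:, None] - 0.5 * lam * lam * g2 * optics.cs_angstrom)
        + optics.phase_shift_rad
        + amplitude_contrast_phase(optics.amplitude_contrast)
    )
    return np.abs(np.sin(phase))


def score_tilt(
    tiles: TileSet,
    optics: OpticsParams,
    theta_deg: float,
    phi_deg: float,
    defocus_avg: float,
) -> float:
    """Mean per-tile NCC between tile profiles and the predicted local models."""
    defoci = local_defocus(
        defocus_avg, theta_deg, phi_deg,
        tiles.centers[:, 0], tiles.centers[:, 1], tiles.pixel_size,
    )
    models = _model_matrix(tiles.freqs, np.asarray(defoci), optics)
    obs = tiles.profiles - tiles.profiles.mean(axis=1, keepdims=True)
    mod = models - models.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(obs, axis=1) * np.linalg.norm(mod, axis=1)
    valid = denom > 0
    if not np.any(valid):
        return 0.0
    ncc = np.einsum("ij,ij->i", obs[valid], mod[valid]) / denom[valid]
    return float(ncc.mean())


def coarse_tilt_search(
    tiles: TileSet,
    optics: OpticsParams,
    defocus_init: float,
    theta_max: float = 70.0,
    phi_step: float = 10.0,
    theta_step: float = 5.0,
) -> TiltResult:
    """Exhaustive scan of the tilt plane: phi in 10-degree, theta in 5-degree steps."""
    best = TiltResult(0.0, 0.0, defocus_init,
                      score_tilt(tiles, optics, 0.0, 0.0, defocus_init))
    for theta in np.arange(theta_step, theta_max + 0.5 * theta_step, theta_step):
        for phi in np.arange(0.0, 360.0, phi_step):
            s = score_tilt(tiles, optics, theta, phi, defocus_init)
            if s > best.score:
                best = TiltResult(float(theta), float(phi), defocus_init, s)
    return best


def refine_tilt(tiles: TileSet, optics: OpticsParams, coarse: TiltResult) -> TiltResult:
    """Simplex refinement of (theta, phi, defocus_avg) from the coarse result.

    The returned score never falls below the coarse score.
    """

    def negscore(x):
        theta, phi, df = x
        return -score_tilt(tiles, optics, theta, phi, df)

    x0 = np.array([coarse.theta_deg, coarse.phi_deg, coarse.defocus_avg])
    steps = np.array([2.5, 5.0, max(50.0, 0.01 * coarse.defocus_avg)])
    simplex = np.vstack([x0] + [x0 + np.eye(3)[i] * steps[i] for i in range(3)])
    res = optimize.minimize(
        negscore, x0, method="Nelder-Mead",
        options={"initial_simplex": simplex, "xatol": 0.05, "fatol": 1e-7,
                 "maxiter": 2000},
    )
    if -res.fun >= coarse.score:
        out = TiltResult(float(res.x[0]), float(res.x[1]), float(res.x[2]),
                         float(-res.fun))
    else:
        out = coarse
    return out.canonicalized()


def tilt_corrected_spectrum(
    image: np.ndarray,
    pixel_size: float,
    tilt: TiltResult,
    out_box: int = 512,
    overlap: float = 0.5,
) -> PowerSpectrum2D:
    """Average power spectrum with per-tile magnification correction.

    Each ``out_box`` tile's amplitude spectrum is resampled radially by
    m = sqrt(df_local / df_avg) (bilinear interpolation) so its Thon rings
    coincide with those of the average defocus, then all tiles are averaged.
    With theta = 0 this reduces to the plain tile average.
    """
    h, w = image.shape
    if out_box > min(h, w):
        raise ValueError(f"out_box {out_box} exceeds image {image.shape}")
    stride = max(1, int(round(out_box * (1.0 - overlap))))
    c = out_box // 2
    grid = np.arange(out_box, dtype=float)
    acc = np.zeros((out_box, out_box))
    n = 0
    cy, cx = h / 2.0, w / 2.0
    for y0 in _tile_starts(h, out_box, stride):
        for x0 in _tile_starts(w, out_box, stride):
            tile = image[y0 : y0 + out_box, x0 : x0 + out_box]
            tile = tile - tile.mean()
            power = np.fft.fftshift(np.abs(np.fft.fft2(tile)) ** 2) / (out_box * out_box)
            df_local = local_defocus(
                tilt.defocus_avg, tilt.theta_deg, tilt.phi_deg,
                x0 + out_box / 2.0 - cx, y0 + out_box / 2.0 - cy, pixel_size,
            )
            m = np.sqrt(max(df_local, 1.0) / tilt.defocus_avg)
            # output ring at g came from the tile's ring at g/m
            coords = c + (grid - c) / m
            yy, xx = np.meshgrid(coords, coords, indexing="ij")
            acc += ndimage.map_coordinates(power, [yy, xx], order=1, mode="nearest")
            n += 1
    return PowerSpectrum2D(np.sqrt(acc / n), pixel_size)
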