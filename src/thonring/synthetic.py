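"""Synthetic micrographs and measurement sets with known ground truth.

Each generator is a forward model of exactly the quantity its estimator
recovers, so recovery tests close the loop without any external data:

* ``synth_micrograph`` filters white Gaussian noise in Fourier space with the
  amplitude of the thin-specimen CTF (or the square root of the thickness-
  modulated power-spectrum model, so the resulting power spectrum follows
  that model), optionally with a per-region defocus following a tilted
  plane, plus additive white noise;
* ``synth_tilt_series`` composes a constant pre-tilt with stage rotations
  about a fixed axis and reports per-image (theta, phi) in the estimator's
  conventions;
* ``synth_attenuation`` draws Beer-Lambert attenuation points with Gaussian
  residuals and a fraction of gross outliers.

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ctf_model import CtfParams, OpticsParams, ctf_thick, ctf_thin
from .tilt import local_defocus
from .tilt_series import TiltSeriesRecord, rotation_from_tilt, tilt_normal

__all__ = [
    "SyntheticSpec",
    "synth_micrograph",
    "synth_tilt_series",
    "synth_attenuation",
]

DEFOCUS_BLOCK = 64  # px; piecewise-constant defocus blocks approximating the plane


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth of one synthetic micrograph.

    ``noise_sigma`` is the RMS of the additive white noise relative to the
    unit-RMS CTF-filtered signal (0.5 by default — strong but realistic
    shot-noise-dominated Thon rings that still average out over tiles).
    """

    size: int = 1024
    pixel_size: float = 1.0
    optics: OpticsParams = field(default_factory=OpticsParams)
    defocus_1: float = 10000.0
    defocus_2: float = 10000.0
    astig_angle_deg: float = 0.0
    tilt_theta_deg: float = 0.0
    tilt_phi_deg: float = 0.0
    thickness: float = 0.0
    noise_sigma: float = 0.5
    seed: int = 0

    @property
    def ctf_params(self) -> CtfParams:
        return CtfParams(
            self.defocus_1, self.defocus_2, self.astig_angle_deg,
            thickness=self.thickness if self.thickness > 0 else None,
            tilt_angle_deg=self.tilt_theta_deg if self.tilt_theta_deg > 0 else None,
            tilt_axis_deg=self.tilt_phi_deg if self.tilt_theta_deg > 0 else None,
        )


def _ctf_amplitude_filter(shape, pixel_size, optics, ctf: CtfParams):
    h, w = shape
    gy = np.fft.fftfreq(h, d=pixel_size)
    gx = np.fft.fftfreq(w, d=pixel_size)
    gyy, gxx = np.meshgrid(gy, gx, indexing="ij")
    g_mag = np.hypot(gxx, gyy)
    g_ang = np.arctan2(gyy, gxx)
    if ctf.thickness is not None and ctf.thickness > 0:
        return np.sqrt(ctf_thick(g_mag, g_ang, optics, ctf))
    return np.abs(ctf_thin(g_mag, g_ang, optics, ctf))


def _filtered_noise(rng, shape, pixel_size, optics, ctf: CtfParams):
    noise = rng.standard_normal(shape)
    filt = _ctf_amplitude_filter(shape, pixel_size, optics, ctf)
    return np.fft.ifft2(np.fft.fft2(noise) * filt).real


def synth_micrograph(spec: SyntheticSpec) -> np.ndarray:
    """Generate a square micrograph whose power spectrum carries the ground truth.

    Untilted specimens are filtered globally; tilted ones block-wise (64-px
    blocks of constant defocus following the tilt plane, blocks much smaller
    than the 128-px analysis tiles).  The signal is normalized to unit RMS
    before white noise of RMS ``noise_sigma`` is added.
    """
    n = spec.size
    rng = np.random.default_rng(spec.seed)
    base = spec.ctf_params
    if spec.tilt_theta_deg == 0.0:
        signal = _filtered_noise(rng, (n, n), spec.pixel_size, spec.optics, base)
    else:
        signal = np.empty((n, n))
        b = DEFOCUS_BLOCK
        for y0 in range(0, n, b):
            for x0 in range(0, n, b):
                by, bx = min(b, n - y0), min(b, n - x0)
                cx = x0 + bx / 2.0 - n / 2.0
                cy = y0 + by / 2.0 - n / 2.0
                df = local_defocus(
                    base.defocus_mean, spec.tilt_theta_deg, spec.tilt_phi_deg,
                    cx, cy, spec.pixel_size,
                )
                astig = base.defocus_1 - base.defocus_2
                block_ctf = CtfParams(
                    df + 0.5 * astig, df - 0.5 * astig, base.astig_angle_deg,
                    thickness=base.thickness,
                )
                signal[y0 : y0 + by, x0 : x0 + bx] = _filtered_noise(
                    rng, (by, bx), spec.pixel_size, spec.optics, block_ctf
                )
    signal /= signal.std()
    return signal + spec.noise_sigma * rng.standard_normal((n, n))


def synth_tilt_series(
    theta0: float,
    phi0: float,
    stage_axis: float,
    nominal_angles,
    noise_deg: float = 0.0,
    seed: int = 0,
):
    """Forward-model a tilt series: records of (nominal angle, theta_i, phi_i).

    Each image's overall orientation is R_i = Rtom_i(nominal, stage_axis) R0;
    the reported (theta_i, phi_i) describe the plane normal R_i [0,0,1]^T in
    the estimator's conventions (theta in [0, 90], phi in [0, 360)), with
    optional Gaussian angular noise applied as a small random rotation of the
    normal.
    """
    rng = np.random.default_rng(seed)
    n0 = tilt_normal(theta0, phi0)
    records = []
    for nominal in np.asarray(nominal_angles, dtype=float):
        rtom = rotation_from_tilt(nominal, stage_axis)
        normal = rtom @ n0
        if noise_deg > 0:
            wobble = rotation_from_tilt(
                rng.normal(0.0, noise_deg), rng.uniform(0.0, 360.0)
            )
            normal = wobble @ normal
        if normal[2] < 0:  # antipodal normal describes the same plane
            normal = -normal
        theta = np.degrees(np.arccos(np.clip(normal[2], -1.0, 1.0)))
        phi = np.degrees(np.arctan2(normal[0], -normal[1])) % 360.0
        records.append(TiltSeriesRecord(float(nominal), float(theta), float(phi)))
    return records


def synth_attenuation(
    kappa: float,
    n_points: int = 500,
    t_range: tuple[float, float] = (500.0, 4000.0),
    outlier_frac: float = 0.1,
    sigma_t: float = 50.0,
    seed: int = 0,
):
    """Beer-Lambert points: t (Angstrom), -ln(I/I0), and the planted-outlier mask.

    Inliers follow -ln(I/I0) = (t + N(0, sigma_t)) / kappa; outliers are
    displaced grossly (uniform offsets of 0.5-2 in -ln(I/I0), random sign).
    """
    rng = np.random.default_rng(seed)
    t = rng.uniform(*t_range, size=n_points)
    y = (t + rng.normal(0.0, sigma_t, size=n_points)) / kappa
    is_outlier = rng.random(n_points) < outlier_frac
    offsets = rng.uniform(0.5, 2.0, size=n_points) * rng.choice([-1.0, 1.0], n_points)
    y = np.where(is_outlier, y + offsets, y)
    return t, y, is_outlier
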