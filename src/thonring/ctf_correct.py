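"""CTF correction of images by phase flipping or a Wiener-like filter.

Medium-magnification overview images (pixel sizes around 40 A, defoci around
200 um) show strong fringes around membranes; multiplying each Fourier
component by the sign of the fitted CTF removes the phase reversals, and a
Wiener-like amplitude correction additionally damps the frequencies where
the CTF transfers little signal, producing a more natural-looking image.
"""

from __future__ import annotations

import numpy as np

from .ctf_model import CtfParams, OpticsParams, ctf_thin

__all__ = ["phase_flip", "wiener_filter"]

DEFAULT_FALLOFF = 1.3
DEFAULT_STRENGTH = 0.7
_NOISE_EPS = 1e-3


def _ctf_grid(shape, pixel_size, optics: OpticsParams, ctf: CtfParams):
    h, w = shape
    gy = np.fft.fftfreq(h, d=pixel_size)
    gx = np.fft.fftfreq(w, d=pixel_size)
    gyy, gxx = np.meshgrid(gy, gx, indexing="ij")
    g_mag = np.hypot(gxx, gyy)
    g_ang = np.arctan2(gyy, gxx)
    return g_mag, ctf_thin(g_mag, g_ang, optics, ctf)


def phase_flip(image, pixel_size: float, optics: OpticsParams, ctf: CtfParams):
    """Multiply each Fourier coefficient by the sign of the CTF.

    An involution (applying it twice restores the image); the DC term is
    passed through with gain +1 so the image mean is preserved.
    """
    image = np.asarray(image, dtype=float)
    _, c = _ctf_grid(image.shape, pixel_size, optics, ctf)
    sign = np.where(c >= 0.0, 1.0, -1.0)
    sign[0, 0] = 1.0
    return np.fft.ifft2(np.fft.fft2(image) * sign).real


def wiener_filter(
    image,
    pixel_size: float,
    optics: OpticsParams,
    ctf: CtfParams,
    falloff: float = DEFAULT_FALLOFF,
    strength: float = DEFAULT_STRENGTH,
):
    """Wiener-like amplitude and phase correction H = C / (C^2 + N).

    The noise term ``N(g) = (1/strength - 1 + eps) * exp(falloff * g/g_nyq)``
    keeps the gain bounded at the CTF zeros and grows with frequency so high
    frequencies are damped; ``strength`` in (0, 1] moves the filter between
    heavy amplitude damping (small values) and aggressive restoration (1).
    The DC term is passed through unchanged.
    """
    if falloff <= 0:
        raise ValueError("falloff must be positive")
    if not (0.0 < strength <= 1.0):
        raise ValueError("strength must be in (0, 1]")
    image = np.asarray(image, dtype=float)
    g_mag, c = _ctf_grid(image.shape, pixel_size, optics, ctf)
    g_nyq = 0.5 / pixel_size
    noise = (1.0 / strength - 1.0 + _NOISE_EPS) * np.exp(falloff * g_mag / g_nyq)
    gain = c / (c * c + noise)
    gain[0, 0] = 1.0
    return np.fft.ifft2(np.fft.fft2(image) * gain).real
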