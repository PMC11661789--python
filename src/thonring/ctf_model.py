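"""Contrast transfer function (CTF) mathematics.

The CTF of a transmission electron microscope modulates image contrast as a
function of spatial frequency ``g``.  For a thin specimen the (phase) CTF is
``-sin(chi)`` where ``chi`` is the aberration phase shift determined by the
electron wavelength, an astigmatic defocus, the spherical aberration and a
constant phase offset contributed by amplitude contrast (and optionally a
phase plate).

For a specimen of appreciable thickness ``t`` the power spectrum is the
defocus average of ``sin^2(chi)`` through the slab, which closes to

    CTF_t(g) = 1/2 * (1 - sinc(xi) * cos(2*chi)),   xi = pi * lambda * g^2 * t

with the unnormalized ``sinc(x) = sin(x)/x``.  ``CTF_t`` oscillates around
0.5, its envelope vanishes at the nodes ``xi = k*pi`` and the Thon rings are
phase-inverted beyond the first node.  The first node frequency therefore
encodes the thickness: ``t = 1/(lambda * g_node^2)``.

Conventions (CTFFIND-style): defoci and thickness in Angstrom, positive
defocus = underfocus, angles in degrees externally / radians internally,
spatial frequencies in 1/Angstrom.  ``defocus_1 >= defocus_2`` with the
astigmatism angle wrapped to (-90, 90] removes the swap/rotate degeneracy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

__all__ = [
    "OpticsParams",
    "CtfParams",
    "electron_wavelength",
    "defocus_at_angle",
    "amplitude_contrast_phase",
    "chi",
    "ctf_thin",
    "xi",
    "ctf_thick",
    "thickness_from_node",
    "first_node_frequency",
]

_MM_TO_ANGSTROM = 1.0e7


def electron_wavelength(voltage_kv: float) -> float:
    """Relativistically corrected electron wavelength in Angstrom.

    lambda = 12.2639 / sqrt(V * (1 + 0.97845e-6 * V)) with V in volts;
    300 kV -> 0.01969 A, 200 kV -> 0.02508 A.
    """
    if voltage_kv <= 0:
        raise ValueError(f"acceleration voltage must be positive, got {voltage_kv} kV")
    v = voltage_kv * 1000.0
    return 12.2639 / np.sqrt(v * (1.0 + 0.97845e-6 * v))


@dataclass(frozen=True)
class OpticsParams:
    """Microscope constants shared by every image of a session.

    Parameters
    ----------
    voltage_kv : acceleration voltage in kV.
    cs_mm : spherical aberration coefficient in mm (stored as given,
        converted to Angstrom where used).
    amplitude_contrast : fraction of amplitude contrast, in [0, 1).
    phase_shift_rad : additional phase shift (phase plate), radians.
    """

    voltage_kv: float = 300.0
    cs_mm: float = 2.7
    amplitude_contrast: float = 0.07
    phase_shift_rad: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude_contrast < 1.0):
            raise ValueError("amplitude_contrast must be in [0, 1)")
        if self.voltage_kv <= 0:
            raise ValueError("voltage_kv must be positive")

    @property
    def wavelength(self) -> float:
        """Electron wavelength in Angstrom."""
        return electron_wavelength(self.voltage_kv)

    @property
    def cs_angstrom(self) -> float:
        return self.cs_mm * _MM_TO_ANGSTROM


@dataclass
class CtfParams:
    """Per-image CTF estimate.

    ``defocus_1 >= defocus_2`` (canonical ordering), both in Angstrom with
    positive = underfocus; ``astig_angle_deg`` is the direction of the
    defocus_1 axis.  Thickness and tilt are optional extensions.
    """

    defocus_1: float
    defocus_2: float
    astig_angle_deg: float = 0.0
    thickness: Optional[float] = None
    tilt_angle_deg: Optional[float] = None
    tilt_axis_deg: Optional[float] = None

    @property
    def defocus_mean(self) -> float:
        return 0.5 * (self.defocus_1 + self.defocus_2)

    def canonicalized(self) -> "CtfParams":
        """Return an equivalent parameter set with defocus_1 >= defocus_2 and
        the astigmatism angle wrapped to (-90, 90]."""
        d1, d2, ang = self.defocus_1, self.defocus_2, self.astig_angle_deg
        if d1 < d2:
            d1, d2 = d2, d1
            ang += 90.0
        ang = (ang + 90.0) % 180.0 - 90.0
        if ang == -90.0:
            ang = 90.0
        return replace(self, defocus_1=d1, defocus_2=d2, astig_angle_deg=ang)


def defocus_at_angle(defocus_1, defocus_2, astig_angle_deg, g_angle_rad):
    """Astigmatic defocus along the spectrum direction ``g_angle_rad``.

    Df(theta_g) = 1/2 [Df1 + Df2 + (Df1 - Df2) cos(2 (theta_g - alpha))].
    """
    alpha = np.deg2rad(astig_angle_deg)
    return 0.5 * (
        defocus_1 + defocus_2
        + (defocus_1 - defocus_2) * np.cos(2.0 * (g_angle_rad - alpha))
    )


def amplitude_contrast_phase(amplitude_contrast: float) -> float:
    """Constant phase offset arctan(w2 / sqrt(1 - w2^2)) from amplitude contrast."""
    w2 = amplitude_contrast
    return float(np.arctan2(w2, np.sqrt(1.0 - w2 * w2)))


def chi(g_mag, g_angle_rad, optics: OpticsParams, ctf: CtfParams):
    """Aberration phase shift chi(g) in radians.

    chi = pi*lambda*g^2 * (Df(theta_g) - 1/2*lambda^2*g^2*Cs)
          + phase_shift + arctan(w2/sqrt(1-w2^2))
    """
    lam = optics.wavelength
    df = defocus_at_angle(ctf.defocus_1, ctf.defocus_2, ctf.astig_angle_deg, g_angle_rad)
    g2 = np.square(g_mag)
    return (
        np.pi * lam * g2 * (df - 0.5 * lam * lam * g2 * optics.cs_angstrom)
        + optics.phase_shift_rad
        + amplitude_contrast_phase(optics.amplitude_contrast)
    )


def ctf_thin(g_mag, g_angle_rad, optics: OpticsParams, ctf: CtfParams):
    """Thin-specimen contrast transfer function -sin(chi), in [-1, 1]."""
    return -np.sin(chi(g_mag, g_angle_rad, optics, ctf))


def xi(g_mag, thickness: float, wavelength: float):
    """Thickness phase spread xi = pi * lambda * g^2 * t (radians)."""
    return np.pi * wavelength * np.square(g_mag) * thickness


def _sinc(x):
    """Unnormalized sinc: sin(x)/x with sinc(0) = 1 (numpy's sinc is normalized)."""
    return np.sinc(np.asarray(x) / np.pi)


def ctf_thick(g_mag, g_angle_rad, optics: OpticsParams, ctf: CtfParams):
    """Thickness-modulated power-spectrum model, in [0, 1].

    CTF_t = 1/2 (1 - sinc(xi) * cos(2*chi)); equals sin^2(chi) in the t -> 0
    limit, crosses 0.5 exactly at every node xi = k*pi, and is phase-inverted
    relative to sin^2(chi) between odd and even nodes.
    """
    if ctf.thickness is None:
        raise ValueError("ctf.thickness must be set for the thick-specimen model")
    c = chi(g_mag, g_angle_rad, optics, ctf)
    x = xi(g_mag, ctf.thickness, optics.wavelength)
    return 0.5 * (1.0 - _sinc(x) * np.cos(2.0 * c))


def thickness_from_node(g_node: float, wavelength: float) -> float:
    """Thickness implied by the first sinc node: t = 1 / (lambda * g_node^2)."""
    if g_node <= 0:
        raise ValueError("node frequency must be positive")
    return 1.0 / (wavelength * g_node * g_node)


def first_node_frequency(thickness: float, wavelength: float) -> float:
    """First node of the sinc envelope: g = 1 / sqrt(lambda * t)."""
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    return 1.0 / np.sqrt(wavelength * thickness)
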