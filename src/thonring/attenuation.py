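"""Beer-Lambert thickness from zero-loss intensity attenuation.

With an energy filter, the fraction of electrons surviving zero-loss
filtering decays exponentially with the thickness traversed:
``-ln(I/I0) = t / kappa`` where ``kappa`` is the apparent mean free path for
inelastic scattering and ``I0`` the vacuum reference intensity.  Plotting
``-ln(I/I0)`` against an independent thickness estimate (e.g. from Thon-ring
node fitting) should give a line of slope ``1/kappa``; a robust RANSAC fit
rejects micrographs whose intensity is corrupted (occluded beam,
contamination, missing signal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LinearRegression, RANSACRegressor

__all__ = [
    "AttenuationPoint",
    "RobustLineFit",
    "thickness_from_attenuation",
    "robust_linear_fit",
]


@dataclass
class AttenuationPoint:
    """One micrograph's intensity ratio and CTF-derived thickness (Angstrom)."""

    intensity_ratio: float  # I / I0
    t_ctf: float
    label: str = "unlabeled"


@dataclass
class RobustLineFit:
    """Consensus line -ln(I/I0) = slope * t + intercept.

    ``kappa`` (= 1/slope) is the apparent mean free path in the units of t;
    ``t_intercept`` is the abscissa intercept (thickness at zero attenuation).
    """

    slope: float
    intercept: float
    inlier_mask: np.ndarray

    @property
    def kappa(self) -> float:
        return 1.0 / self.slope

    @property
    def t_intercept(self) -> float:
        return -self.intercept / self.slope


def thickness_from_attenuation(intensity, vacuum_intensity, kappa: float):
    """Thickness t = -kappa * ln(I / I0); negative when I > I0 (flagged upstream)."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0) or vacuum_intensity <= 0 or kappa <= 0:
        raise ValueError("intensities and kappa must be positive")
    return -kappa * np.log(intensity / vacuum_intensity)


def robust_linear_fit(
    t_ctf,
    neg_log_ratio,
    seed: int = 0,
    residual_threshold: float | None = None,
    max_trials: int = 1000,
) -> RobustLineFit:
    """RANSAC consensus line through (t_ctf, -ln(I/I0)).

    Repeated minimal-sample fits keep the line with the largest inlier set
    (residuals within a MAD-based threshold by default), then the final line
    is an ordinary least-squares fit on the consensus set.  With zero noise
    and no outliers this coincides exactly with plain least squares.
    """
    t = np.asarray(t_ctf, dtype=float).reshape(-1, 1)
    y = np.asarray(neg_log_ratio, dtype=float)
    if t.shape[0] < 10:
        raise ValueError("need at least 10 points for a robust fit")
    ransac = RANSACRegressor(
        estimator=LinearRegression(),
        residual_threshold=residual_threshold,  # None -> sklearn's MAD default
        max_trials=max_trials,
        random_state=seed,
    )
    ransac.fit(t, y)
    mask = ransac.inlier_mask_
    if mask.sum() < 0.5 * len(y):
        raise ValueError("no consensus: fewer than 50% inliers")
    final = LinearRegression().fit(t[mask], y[mask])
    return RobustLineFit(
        slope=float(final.coef_[0]),
        intercept=float(final.intercept_),
        inlier_mask=mask,
    )
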