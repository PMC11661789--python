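"""Pre-tilt and stage-axis geometry from per-image tilt estimates.

FIB-milled lamellae carry an intrinsic pre-tilt (from the milling angle)
whose direction generally does not coincide with the goniometer tilt axis.
Given per-image estimates (theta_i, phi_i) of the overall specimen tilt and
the nominal stage angle of each image, the overall orientation decomposes as

    R_i = Rtom_i x R0

with Rtom_i the stage rotation (nominal angle about the stage axis) and R0
the constant pre-tilt.  Per-image pre-tilt estimates follow as
R0_i = Rtom_i^T R_i; their plane normals R0_i [0,0,1]^T should agree, so the
stage-axis angle is found by minimizing the spread of those normals over a
fine 1D grid, outliers are rejected against the RMSD of the normals, and the
pre-tilt (theta_0, phi_0) is read off the mean normal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TiltSeriesRecord",
    "PreTiltModel",
    "rotation_from_tilt",
    "pre_tilt_per_image",
    "mean_normal",
    "pre_tilt_from_normal",
    "fit_tilt_model",
]

MIN_RELIABLE_AXIS_THETA = 5.0  # degrees; below this the estimated axis is noise


@dataclass
class TiltSeriesRecord:
    """One image of a tilt series: nominal stage angle plus estimated tilt."""

    nominal_stage_angle: float  # degrees, signed
    est_theta: float  # degrees in [0, 90]
    est_phi: float  # degrees in [0, 360)


@dataclass
class PreTiltModel:
    """Fitted geometry: specimen pre-tilt (theta0, phi0) and stage-axis angle."""

    theta0: float
    phi0: float
    stage_axis: float
    residuals_deg: np.ndarray  # per-image angular deviation of the normal
    inlier_mask: np.ndarray
    axis_reliable: np.ndarray = field(default_factory=lambda: np.array([], bool))


def rotation_from_tilt(theta_deg, phi_deg) -> np.ndarray:
    """Rotation by ``theta`` about the in-plane axis at angle ``phi``.

    Accepts scalars or equal-length arrays; returns (3, 3) or (n, 3, 3).
    The matrix is orthonormal with determinant +1 and collapses to the
    identity at theta = 0.
    """
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    ct, st = np.cos(theta), np.sin(theta)
    cp, sp = np.cos(phi), np.sin(phi)
    R = np.empty(np.broadcast(ct, cp).shape + (3, 3))
    R[..., 0, 0] = cp * cp + sp * sp * ct
    R[..., 0, 1] = cp * sp * (1.0 - ct)
    R[..., 0, 2] = sp * st
    R[..., 1, 0] = cp * sp * (1.0 - ct)
    R[..., 1, 1] = cp * cp * ct + sp * sp
    R[..., 1, 2] = -cp * st
    R[..., 2, 0] = -sp * st
    R[..., 2, 1] = cp * st
    R[..., 2, 2] = ct
    return R


def tilt_normal(theta_deg, phi_deg) -> np.ndarray:
    """Plane normal of a tilt: R(theta, phi) [0,0,1]^T."""
    theta = np.deg2rad(np.asarray(theta_deg, dtype=float))
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    return np.stack(
        [np.sin(phi) * np.sin(theta), -np.cos(phi) * np.sin(theta),
         np.cos(theta)], axis=-1,
    )


def pre_tilt_per_image(record: TiltSeriesRecord, stage_axis: float) -> np.ndarray:
    """Per-image pre-tilt rotation R0_i = Rtom_i^T R_i."""
    rtom = rotation_from_tilt(record.nominal_stage_angle, stage_axis)
    ri = rotation_from_tilt(record.est_theta, record.est_phi)
    return rtom.T @ ri


def mean_normal(rotations, rmsd_cutoff: float = 2.0):
    """Unit mean of the plane normals with one round of RMSD outlier rejection.

    Normals deviating from the mean by more than ``rmsd_cutoff`` times the
    RMSD of all deviations are excluded and the mean recomputed once.
    Returns ``(mean_unit_normal, inlier_mask)``.
    """
    rotations = np.asarray(rotations)
    if rotations.shape[0] < 3:
        raise ValueError("need at least 3 rotations")
    normals = rotations[..., :, 2]  # R [0,0,1]^T is the third column
    mean = _unit_mean(normals)
    dev = np.linalg.norm(normals - mean, axis=1)
    rmsd = float(np.sqrt(np.mean(dev**2)))
    if rmsd > 0:
        mask = dev <= rmsd_cutoff * rmsd
    else:
        mask = np.ones(len(normals), bool)
    if not np.any(mask):
        raise ValueError("all normals rejected as outliers")
    mean = _unit_mean(normals[mask])
    return mean, mask


def _unit_mean(normals: np.ndarray) -> np.ndarray:
    m = normals.mean(axis=0)
    norm = np.linalg.norm(m)
    if norm == 0:
        raise ValueError("degenerate (zero) mean normal")
    return m / norm


def pre_tilt_from_normal(v) -> tuple[float, float]:
    """Pre-tilt angles from a unit plane normal [x0, y0, z0].

    theta0 = +-acos(z0) with the sign of x0; phi0 = atan(-x0/y0) mapped into
    [0, 180] degrees, with phi0 = 90 when y0 = 0.
    """
    x0, y0, z0 = np.asarray(v, dtype=float)
    theta0 = np.degrees(np.arccos(np.clip(z0, -1.0, 1.0)))
    if x0 < 0:
        theta0 = -theta0
    if y0 == 0.0:
        phi0 = 90.0 if x0 != 0.0 else 0.0
    else:
        phi0 = np.degrees(np.arctan(-x0 / y0))
        if phi0 < 0.0:
            phi0 += 180.0
    return float(theta0), float(phi0)


def _normal_spread(normals: np.ndarray, nominal: np.ndarray, axis: float) -> float:
    """RMS deviation of the back-rotated normals about their mean."""
    rtom = rotation_from_tilt(nominal, np.full_like(nominal, axis))
    back = np.einsum("nji,nj->ni", rtom, normals)  # Rtom^T n
    mean = _unit_mean(back)
    return float(np.sqrt(np.mean(np.sum((back - mean) ** 2, axis=1))))


def fit_tilt_model(
    records,
    rmsd_cutoff: float = 2.0,
    axis_step_fine: float = 0.1,
) -> PreTiltModel:
    """Fit a constant pre-tilt plus a single stage tilt axis to a series.

    Scans the stage-axis angle over [0, 360) (coarse 1-degree grid, then the
    requested fine grid around the minimum with a final parabolic
    refinement), minimizing the spread of the per-image pre-tilt normals.
    Outliers beyond ``rmsd_cutoff`` x RMSD are excluded once and the model
    recomputed.  Images with estimated tilt under 5 degrees are flagged
    ``axis_reliable = False``: their axis estimate carries almost no signal.
    """
    records = list(records)
    if len(records) < 5:
        raise ValueError(f"need at least 5 records, got {len(records)}")
    nominal = np.array([r.nominal_stage_angle for r in records], float)
    theta = np.array([r.est_theta for r in records], float)
    phi = np.array([r.est_phi for r in records], float)
    normals = tilt_normal(theta, phi)

    def spread(axis: float) -> float:
        return _normal_spread(normals, nominal, axis)

    coarse = np.arange(0.0, 360.0, 1.0)
    best = float(coarse[np.argmin([spread(a) for a in coarse])])
    fine = np.arange(best - 1.5, best + 1.5 + 0.5 * axis_step_fine, axis_step_fine)
    fine_scores = np.array([spread(a) for a in fine])
    i = int(np.argmin(fine_scores))
    axis = float(fine[i])
    if 0 < i < len(fine) - 1:  # parabolic vertex through the three best samples
        y0, y1, y2 = fine_scores[i - 1 : i + 2]
        denom = y0 - 2.0 * y1 + y2
        if denom > 0:
            axis += axis_step_fine * 0.5 * (y0 - y2) / denom
    axis %= 360.0

    rtom = rotation_from_tilt(nominal, np.full_like(nominal, axis))
    back = np.einsum("nji,nj->ni", rtom, normals)
    # reuse mean_normal's rejection logic by faking rotations whose 3rd column
    # is each back-rotated normal
    fake = np.zeros((len(back), 3, 3))
    fake[:, :, 2] = back
    mean, mask = mean_normal(fake, rmsd_cutoff)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 inlier records after outlier rejection")
    theta0, phi0 = pre_tilt_from_normal(mean)
    cosang = np.clip(back @ mean, -1.0, 1.0)
    residuals = np.degrees(np.arccos(cosang))
    return PreTiltModel(
        theta0=theta0,
        phi0=phi0,
        stage_axis=axis,
        residuals_deg=residuals,
        inlier_mask=mask,
        axis_reliable=np.abs(theta) >= MIN_RELIABLE_AXIS_THETA,
    )
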