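"""Inverse kinematics of the planar leg.

Per frame, the hip and knee angles are fitted by least squares so the model
knee and ankle centres match the tracked positions, with the model hip
riding on the tracked hip (prescribed base translation).  Tracked data can
show the limb from either side of the image plane; when the recovered knee
flexion is predominantly negative the trajectories are mirrored across the
horizontal axis through the mean hip position so that the pose matches the
model's anatomical flexion convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ..errors import ConfigurationError
from .model import SkeletonModel


@dataclass
class JointAngleSeries:
    alpha: np.ndarray        # (n,) world femur angle, rad
    phi: np.ndarray          # (n,) knee flexion, rad
    psi: float               # locked ankle angle, rad
    hip: np.ndarray          # (n, 2) hip positions, m
    residual_mm: np.ndarray  # (n,) RMS joint-fit residual
    mirrored: bool = False

    def q(self, i: int) -> np.ndarray:
        return np.array([self.alpha[i], self.phi[i], self.psi])

    def __len__(self) -> int:
        return len(self.alpha)


def _initial_angles(hip, knee, ankle):
    d_f = knee - hip
    d_t = ankle - knee
    if np.linalg.norm(d_f) < 1e-12 or np.linalg.norm(d_t) < 1e-12:
        raise ConfigurationError("degenerate (zero-length) configuration")
    alpha = np.arctan2(d_f[1], d_f[0])
    # knee flexion is the clockwise angle from the femur to the tibia
    cross = d_f[0] * d_t[1] - d_f[1] * d_t[0]
    phi = -np.arctan2(cross, np.dot(d_f, d_t))
    return alpha, phi


def inverse_kinematics(model: SkeletonModel, hip_mm: np.ndarray,
                       knee_mm: np.ndarray, ankle_mm: np.ndarray,
                       auto_mirror: bool = True) -> JointAngleSeries:
    """Fit hip/knee angles to tracked joint positions (mm in, angles out)."""
    hip = np.asarray(hip_mm, float) * 1e-3
    knee = np.asarray(knee_mm, float) * 1e-3
    ankle = np.asarray(ankle_mm, float) * 1e-3
    if not (len(hip) == len(knee) == len(ankle)):
        raise ConfigurationError("trajectories must have equal lengths")

    mirrored = False
    if auto_mirror:
        phi0 = np.array([
            _initial_angles(hip[i], knee[i], ankle[i])[1]
            for i in range(len(hip))
        ])
        if np.median(phi0) < 0:
            y0 = hip[:, 1].mean()
            for arr in (hip, knee, ankle):
                arr[:, 1] = 2 * y0 - arr[:, 1]
            mirrored = True

    psi = model.ankle_locked_angle
    n = len(hip)
    alpha = np.empty(n)
    phi = np.empty(n)
    res = np.empty(n)
    for i in range(n):
        a0, p0 = _initial_angles(hip[i], knee[i], ankle[i])

        def fun(q, i=i):
            k, a, _ = model.joint_positions(hip[i], np.array([q[0], q[1], psi]))
            return np.concatenate([k - knee[i], a - ankle[i]])

        sol = least_squares(fun, x0=[a0, p0], xtol=1e-14, ftol=1e-14,
                            gtol=1e-14)
        alpha[i], phi[i] = sol.x
        res[i] = float(np.sqrt(np.mean(sol.fun**2))) * 1e3
    return JointAngleSeries(alpha=alpha, phi=phi, psi=psi, hip=hip,
                            residual_mm=res, mirrored=mirrored)
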