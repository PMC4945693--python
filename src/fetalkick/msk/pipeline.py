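"""End-of-chain orchestration: tracked kick -> muscle force series."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .dynamics import inverse_dynamics
from .kinematics import inverse_kinematics
from .model import SkeletonModel
from .optimization import MuscleForceSeries, static_optimization


@dataclass
class KickInput:
    """Joint trajectories plus the wall reaction applied at the calcaneus.

    Positions are mm in the imaging frame; ``force_n`` is the per-frame
    reaction force vector on the foot (zero outside the contact window).
    """

    hip_mm: np.ndarray
    knee_mm: np.ndarray
    ankle_mm: np.ndarray
    force_n: np.ndarray          # (n, 2)
    frame_interval_s: float

    def __post_init__(self):
        n = len(self.hip_mm)
        if not (len(self.knee_mm) == len(self.ankle_mm)
                == len(self.force_n) == n):
            raise ConfigurationError(
                "trajectories and force series must have equal lengths"
            )


@dataclass
class KickResult:
    angles: object               # JointAngleSeries
    moments_nm: np.ndarray       # (n, 3)
    forces: MuscleForceSeries

    @property
    def maxima_table(self) -> list:
        """Rows (muscle, group, max_force_N), knee group first, descending."""
        rows = [
            (nm, g, self.forces.per_muscle_max[nm])
            for nm, g in zip(self.forces.names, self.forces.groups)
        ]
        return sorted(rows, key=lambda r: (r[1] != "knee", -r[2]))


def ramped_contact_force(deflection_mm: np.ndarray, peak_force_n: float,
                         direction) -> np.ndarray:
    """Per-frame calcaneus force following the wall deflection profile.

    The FE reaction grows essentially in proportion to the indentation, so
    the per-frame force is the peak FE contact force scaled by the current
    fraction of the maximal deflection, directed along ``direction`` (the
    inward wall normal: the wall pushes back on the foot).
    """
    deflection_mm = np.asarray(deflection_mm, float)
    peak = deflection_mm.max()
    frac = deflection_mm / peak if peak > 0 else np.zeros_like(deflection_mm)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return frac[:, None] * peak_force_n * d[None, :]


def _anchor_to_pelvis_frame(kick: KickInput):
    """Rotate the kick into the model's pelvis frame.

    The imaging frame has no anatomical axes; the model's pelvis segment
    is vertical with the leg hanging along -y at neutral.  Rotating all
    positions (about the mean hip) so the mean femur direction points
    down puts the pose in the anatomical range where the bundled muscle
    geometry is valid.  Forces rotate with the frame.
    """
    hip = np.asarray(kick.hip_mm, float)
    knee = np.asarray(kick.knee_mm, float)
    ankle = np.asarray(kick.ankle_mm, float)
    force = np.asarray(kick.force_n, float)
    d = (knee - hip).mean(axis=0)
    rho = -np.pi / 2 - np.arctan2(d[1], d[0])
    R = np.array([[np.cos(rho), -np.sin(rho)], [np.sin(rho), np.cos(rho)]])
    c = hip.mean(axis=0)
    rot = lambda p: (p - c) @ R.T + c
    return rot(hip), rot(knee), rot(ankle), force @ R.T


def run_kick(model: SkeletonModel, kick: KickInput) -> KickResult:
    """Inverse kinematics -> inverse dynamics -> static optimization."""
    hip_mm, knee_mm, ankle_mm, force = _anchor_to_pelvis_frame(kick)
    angles = inverse_kinematics(model, hip_mm, knee_mm, ankle_mm)
    force = force.copy()
    if angles.mirrored:
        force[:, 1] = -force[:, 1]
    moments = inverse_dynamics(model, angles, force, kick.frame_interval_s)
    forces = static_optimization(moments, model, angles)
    return KickResult(angles=angles, moments_nm=moments, forces=forces)
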