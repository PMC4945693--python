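"""Quadratic static optimization of muscle redundancy.

Per frame, activations a minimize  sum(a^2) + w * sum((reserve/ref)^2)
subject to the joint-moment balance  R @ (Fmax * a) + reserve = M  with
0 <= a <= 1, where R holds tendon-excursion moment arms.  Eliminating the
reserves turns this into a bound-constrained linear least-squares problem
solved with scipy's bounded lsq solver; reserves absorb whatever moment
the muscles cannot produce and are heavily penalized, mirroring reserve
actuators in standard musculoskeletal pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from ..errors import ConfigurationError
from .kinematics import JointAngleSeries
from .model import SkeletonModel

RESERVE_REF_NM = 1e-3     # 1 N*mm reference reserve magnitude
RESERVE_WEIGHT = 1e3


@dataclass
class MuscleForceSeries:
    names: list
    groups: list
    activations: np.ndarray   # (n, nm) in [0, 1]
    forces_n: np.ndarray      # (n, nm) = activations * fmax
    reserves_nm: np.ndarray   # (n, 3) reserve moments, N*m
    high_reserve_frames: np.ndarray  # frames where a reserve > 1% of |M|

    @property
    def per_muscle_max(self) -> dict:
        return {nm: float(self.forces_n[:, j].max())
                for j, nm in enumerate(self.names)}

    def group_max(self, group: str) -> float:
        sel = [j for j, g in enumerate(self.groups) if g == group]
        if not sel:
            return 0.0
        return float(self.forces_n[:, sel].max())


def solve_frame(R_torque: np.ndarray, moments: np.ndarray,
                weight: float = RESERVE_WEIGHT,
                ref: float = RESERVE_REF_NM) -> tuple[np.ndarray, np.ndarray]:
    """One static-optimization solve.

    R_torque[i, j] = r_ij * Fmax_j (moment produced by muscle j at full
    activation about constraint row i); moments: (nrows,).  Returns
    (activations, reserves).
    """
    nrows, nm = R_torque.shape
    s = np.sqrt(weight) / ref
    A = np.vstack([s * R_torque, np.eye(nm)])
    b = np.concatenate([s * moments, np.zeros(nm)])
    sol = lsq_linear(A, b, bounds=(0.0, 1.0), tol=1e-14, max_iter=500)
    a = sol.x
    reserves = moments - R_torque @ a
    return a, reserves


def static_optimization(moments: np.ndarray, model: SkeletonModel,
                        angles: JointAngleSeries,
                        weight: float = RESERVE_WEIGHT,
                        ref: float = RESERVE_REF_NM) -> MuscleForceSeries:
    """Resolve per-frame joint moments (n, 3) into muscle forces."""
    moments = np.asarray(moments, float)
    n = len(angles)
    if moments.shape[0] != n:
        raise ConfigurationError("moment series length mismatch")
    fmax = np.array([m.fmax_n for m in model.muscles])
    nm = len(fmax)
    acts = np.empty((n, nm))
    reserves = np.empty((n, moments.shape[1]))
    for i in range(n):
        R = model.moment_arms(angles.q(i))          # (3, nm)
        a, res = solve_frame(R * fmax[None, :], moments[i], weight, ref)
        acts[i] = a
        reserves[i] = res
    forces = acts * fmax[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(reserves) / np.maximum(np.abs(moments), 1e-12)
    high = np.where(rel.max(axis=1) > 0.01)[0]
    return MuscleForceSeries(
        names=[m.name for m in model.muscles],
        groups=[m.group for m in model.muscles],
        activations=acts, forces_n=forces, reserves_nm=reserves,
        high_reserve_frames=high,
    )
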