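"""Inverse dynamics of the planar leg (gravity neglected).

Joint moments are the generalized torques the muscles must supply about
(hip, knee, locked ankle).  They are computed by d'Alembert's principle:
inertial forces of each segment and the external calcaneus force are
projected onto the generalized coordinates through position Jacobians
evaluated by central differences on the forward kinematics.  Gravity is
omitted because the fetus is near neutrally buoyant in amniotic fluid.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError
from .kinematics import JointAngleSeries
from .model import SEGMENTS, SkeletonModel

_MOVING = ("femur", "tibia", "foot")


def _com_and_angle(model: SkeletonModel, hip, q):
    frames = model.segment_frames(hip, q)
    coms, angs = {}, {}
    for s in _MOVING:
        prox, d = frames[s]
        seg = model.segments[s]
        coms[s] = prox + seg.com_frac * seg.length_m * d
        angs[s] = np.arctan2(d[1], d[0])
    return coms, angs


def _finite_diff(series: np.ndarray, dt: float) -> np.ndarray:
    """Second time derivative; central inside, one-sided at the ends."""
    n = len(series)
    out = np.zeros_like(series)
    if n < 3:
        raise ConfigurationError("need >= 3 frames to differentiate twice")
    out[1:-1] = (series[2:] - 2 * series[1:-1] + series[:-2]) / dt**2
    out[0] = out[1]
    out[-1] = out[-2]
    return out


def inverse_dynamics(model: SkeletonModel, angles: JointAngleSeries,
                     external_force_n: np.ndarray, dt: float,
                     h: float = 1e-6) -> np.ndarray:
    """Generalized joint moments (n, 3) in N*m for (hip, knee, ankle).

    ``external_force_n`` is the per-frame force applied at the calcaneus,
    shape (n, 2), in the same world frame as the kinematics.
    """
    n = len(angles)
    F = np.asarray(external_force_n, float)
    if F.shape != (n, 2):
        raise ConfigurationError("force series must have shape (n_frames, 2)")
    if n < 3:
        raise ConfigurationError("need >= 3 frames for inverse dynamics")

    coms = {s: np.empty((n, 2)) for s in _MOVING}
    angs = {s: np.empty(n) for s in _MOVING}
    for i in range(n):
        c, a = _com_and_angle(model, angles.hip[i], angles.q(i))
        for s in _MOVING:
            coms[s][i] = c[s]
            angs[s][i] = np.unwrap([a[s]])[0]
    for s in _MOVING:
        angs[s] = np.unwrap(angs[s])
    acc = {s: _finite_diff(coms[s], dt) for s in _MOVING}
    alp = {s: _finite_diff(angs[s], dt) for s in _MOVING}

    tau = np.zeros((n, 3))
    for i in range(n):
        qi = angles.q(i)
        hip_i = angles.hip[i]
        for k in range(3):
            qp, qm = qi.copy(), qi.copy()
            qp[k] += h
            qm[k] -= h
            cp, ap = _com_and_angle(model, hip_i, qp)
            cm, am = _com_and_angle(model, hip_i, qm)
            t = 0.0
            for s in _MOVING:
                seg = model.segments[s]
                Jr = (cp[s] - cm[s]) / (2 * h)
                Ja = (ap[s] - am[s]) / (2 * h)
                t += seg.mass_kg * acc[s][i] @ Jr + seg.inertia * alp[s][i] * Ja
            # external force contribution through the calcaneus Jacobian
            rp = model.calcaneus_position(hip_i, qp)
            rm = model.calcaneus_position(hip_i, qm)
            Jc = (rp - rm) / (2 * h)
            t -= F[i] @ Jc
            tau[i, k] = t
    return tau
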