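"""Planar leg skeleton with via-point muscle paths.

The model reduces an adult lower-limb musculoskeletal model to the sagittal
plane: pelvis fixed to ground (apart from a prescribed hip translation),
hip as a planar revolute, knee as a hinge, ankle locked at a constant
angle.  Muscles are polylines through via points attached to segments;
moment arms follow from the tendon-excursion relation r = -dL/dq.

Generalized coordinates (radians):
  alpha — world angle of the femur axis (counter-clockwise; hip flexion
          increases alpha),
  phi   — knee flexion (0 = straight leg, positive = anatomical flexion),
  psi   — ankle angle (pi/2 = foot perpendicular to the tibia, toes
          anterior; smaller = plantarflexed).  Locked during a kick.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from ..errors import ConfigurationError

SEGMENTS = ("pelvis", "femur", "tibia", "foot")


def _rot(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _perp(d: np.ndarray) -> np.ndarray:
    return np.array([-d[1], d[0]])


@dataclass(frozen=True)
class Segment:
    name: str
    length_m: float
    mass_kg: float
    com_frac: float = 0.4           # along the axis from the proximal joint
    # slender-rod planar inertia about the centre of mass
    @property
    def inertia(self) -> float:
        return self.mass_kg * self.length_m**2 / 12.0


@dataclass(frozen=True)
class MuscleDef:
    name: str
    group: str                       # "hip" | "knee"
    fmax_n: float
    path: tuple                      # ((segment, frac, offset_m), ...)

    def __post_init__(self):
        if self.fmax_n <= 0:
            raise ConfigurationError(f"{self.name}: fmax must be > 0")
        if len(self.path) < 2:
            raise ConfigurationError(f"{self.name}: needs >= 2 path points")
        if len({p[0] for p in self.path}) < 2:
            raise ConfigurationError(f"{self.name}: must span >= 2 segments")


@dataclass(frozen=True)
class SkeletonModel:
    segments: dict                    # name -> Segment
    muscles: tuple                    # MuscleDef
    ankle_locked_angle: float = np.pi / 2
    calcaneus_foot: tuple = (-0.18, -0.04)  # (frac along foot axis, offset frac of foot length)

    def __post_init__(self):
        for s in SEGMENTS:
            if s not in self.segments:
                raise ConfigurationError(f"missing segment '{s}'")
            if self.segments[s].length_m <= 0:
                raise ConfigurationError(f"segment '{s}' length must be > 0")
            if self.segments[s].mass_kg < 0:
                raise ConfigurationError(f"segment '{s}' mass must be >= 0")

    # ---------------- forward kinematics ----------------
    def joint_positions(self, hip: np.ndarray, q: np.ndarray):
        """World positions of knee, ankle, toe for q = (alpha, phi, psi)."""
        alpha, phi, psi = q
        d_f = np.array([np.cos(alpha), np.sin(alpha)])
        d_t = _rot(-phi) @ d_f
        d_ft = _rot(psi) @ d_t
        knee = hip + self.segments["femur"].length_m * d_f
        ankle = knee + self.segments["tibia"].length_m * d_t
        toe = ankle + self.segments["foot"].length_m * d_ft
        return knee, ankle, toe

    def segment_frames(self, hip: np.ndarray, q: np.ndarray):
        """(proximal point, axis direction) per segment in the world frame."""
        alpha, phi, psi = q
        d_f = np.array([np.cos(alpha), np.sin(alpha)])
        d_t = _rot(-phi) @ d_f
        d_ft = _rot(psi) @ d_t
        knee = hip + self.segments["femur"].length_m * d_f
        ankle = knee + self.segments["tibia"].length_m * d_t
        return {
            "pelvis": (hip, np.array([0.0, 1.0])),
            "femur": (hip, d_f),
            "tibia": (knee, d_t),
            "foot": (ankle, d_ft),
        }

    def point_on_segment(self, frames: dict, segment: str, frac: float,
                         offset_m: float) -> np.ndarray:
        prox, d = frames[segment]
        L = self.segments[segment].length_m
        return prox + frac * L * d + offset_m * _perp(d)

    def calcaneus_position(self, hip: np.ndarray, q: np.ndarray) -> np.ndarray:
        frames = self.segment_frames(hip, q)
        frac, off = self.calcaneus_foot
        L = self.segments["foot"].length_m
        return self.point_on_segment(frames, "foot", frac, off * L)

    def muscle_length(self, hip: np.ndarray, q: np.ndarray,
                      muscle: MuscleDef) -> float:
        frames = self.segment_frames(hip, q)
        pts = np.array([
            self.point_on_segment(frames, seg, frac, off)
            for seg, frac, off in muscle.path
        ])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def moment_arms(self, q: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Tendon-excursion moment arms r[i, j] = -dL_j/dq_i, shape (3, nm)."""
        hip = np.zeros(2)
        out = np.empty((3, len(self.muscles)))
        for i in range(3):
            qp, qm = q.copy(), q.copy()
            qp[i] += h
            qm[i] -= h
            for j, m in enumerate(self.muscles):
                Lp = self.muscle_length(hip, qp, m)
                Lm = self.muscle_length(hip, qm, m)
                out[i, j] = -(Lp - Lm) / (2 * h)
        return out


def reference_model() -> SkeletonModel:
    """Adult-scale reference (segment lengths in metres, masses in kg)."""
    segments = {
        "pelvis": Segment("pelvis", 0.170, 11.78),
        "femur": Segment("femur", 0.396, 9.30),
        "tibia": Segment("tibia", 0.430, 3.71),
        "foot": Segment("foot", 0.250, 1.48),
    }
    return SkeletonModel(segments=segments, muscles=load_muscles())


def load_muscles() -> tuple:
    """The bundled 18-muscle planar set (adult scale)."""
    data = resources.files("fetalkick.data")
    with resources.as_file(data / "muscles.csv") as p:
        base = pd.read_csv(p, comment="#")
    with resources.as_file(data / "muscle_paths.csv") as p:
        paths = pd.read_csv(p, comment="#")
    muscles = []
    for _, row in base.iterrows():
        sub = paths[paths["name"] == row["name"]].sort_values("seq")
        if sub.empty:
            raise ConfigurationError(f"no path for muscle '{row['name']}'")
        path = tuple(
            (r["segment"], float(r["frac"]), float(r["offset_mm"]) * 1e-3)
            for _, r in sub.iterrows()
        )
        muscles.append(MuscleDef(name=row["name"], group=row["group"],
                                 fmax_n=float(row["fmax_n"]), path=path))
    return tuple(muscles)


def scale_model(reference: SkeletonModel, femur_mm: float,
                tibia_mm: float) -> SkeletonModel:
    """Scale the reference skeleton to measured femur/tibia lengths.

    Femur and tibia scale by their own factors; pelvis and foot by the
    mean factor.  Masses scale with factor cubed, muscle path offsets with
    their segment's factor (fractional coordinates are preserved), and
    maximum isometric forces are left unchanged.
    """
    if femur_mm <= 0 or tibia_mm <= 0:
        raise ConfigurationError("segment lengths must be positive")
    f_fem = femur_mm * 1e-3 / reference.segments["femur"].length_m
    f_tib = tibia_mm * 1e-3 / reference.segments["tibia"].length_m
    f_mean = 0.5 * (f_fem + f_tib)
    factors = {"pelvis": f_mean, "femur": f_fem, "tibia": f_tib,
               "foot": f_mean}
    segments = {
        name: replace(seg, length_m=seg.length_m * factors[name],
                      mass_kg=seg.mass_kg * factors[name] ** 3)
        for name, seg in reference.segments.items()
    }
    muscles = tuple(
        replace(m, path=tuple(
            (seg, frac, off * factors[seg]) for seg, frac, off in m.path
        ))
        for m in reference.muscles
    )
    return replace(reference, segments=segments, muscles=muscles)
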