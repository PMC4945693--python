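"""Kick scenarios: per-fetus geometry and kinematic parameters.

A :class:`KickScenario` bundles everything the synthetic generator needs to
produce one ground-truthed kick sequence: limb segment lengths, the outer
uterine-wall ellipse, the maximal wall deflection reached by the kick, and
the acquisition parameters of the emulated cine series (frame interval
0.303 s, in-plane pixel 2.2 mm).

:func:`default_cohort` returns the three study fetuses (20-22 gestational
weeks) whose measurements drive every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml

from .errors import ConfigurationError, ParseError

# wall build-up used consistently across rendering, tracking and FE:
# thin fetal membrane lining the cavity plus the uterine muscle layer
MEMBRANE_THICKNESS_MM = 0.6
MUSCLE_THICKNESS_MM = 6.0
WALL_THICKNESS_MM = MEMBRANE_THICKNESS_MM + MUSCLE_THICKNESS_MM


@dataclass(frozen=True)
class KickScenario:
    """Geometric and kinematic description of one fetal kick."""

    name: str
    gestational_age_weeks: float
    femur_length_mm: float
    tibia_length_mm: float
    uterus_major_axis_mm: float  # outer-wall ellipse, full axis
    uterus_minor_axis_mm: float
    max_deflection_mm: float
    kick_duration_s: float
    frame_interval_s: float = 0.303
    pixel_size_mm: float = 2.2
    noise_sd: float = 0.05       # fraction of rendered dynamic range
    blur_sigma_mm: float = 1.5
    hip_drift_mm: float = 0.5    # residual hip motion amplitude
    # perpendicular offset of the hip from the push line; the kick then
    # demands a net hip-flexion moment, as described for kicks in utero
    hip_lateral_offset_mm: float = 4.0
    contact_theta: float = 0.25 * 3.141592653589793  # parametric contact angle
    contact_fraction: float = 0.5  # fraction of the sequence before first contact
    rng_seed: int = 0

    def __post_init__(self):
        pos = {
            "femur_length_mm": self.femur_length_mm,
            "tibia_length_mm": self.tibia_length_mm,
            "uterus_major_axis_mm": self.uterus_major_axis_mm,
            "uterus_minor_axis_mm": self.uterus_minor_axis_mm,
            "kick_duration_s": self.kick_duration_s,
            "frame_interval_s": self.frame_interval_s,
            "pixel_size_mm": self.pixel_size_mm,
        }
        for field, value in pos.items():
            if not value > 0:
                raise ConfigurationError(f"{field} must be > 0, got {value}")
        if self.max_deflection_mm < 0:
            raise ConfigurationError("max_deflection_mm must be >= 0")
        if self.noise_sd < 0 or self.blur_sigma_mm < 0:
            raise ConfigurationError("noise_sd and blur_sigma_mm must be >= 0")
        limb = self.femur_length_mm + self.tibia_length_mm
        if not limb < self.uterus_minor_axis_mm:
            raise ConfigurationError(
                f"limb (femur+tibia = {limb:.2f} mm) does not fit inside the "
                f"uterus minor axis ({self.uterus_minor_axis_mm:.2f} mm)"
            )
        if not 0.0 < self.contact_fraction < 1.0:
            raise ConfigurationError("contact_fraction must be in (0, 1)")

    # -- derived geometry -------------------------------------------------
    @property
    def outer_semi_axes(self) -> tuple[float, float]:
        return self.uterus_major_axis_mm / 2.0, self.uterus_minor_axis_mm / 2.0

    @property
    def inner_semi_axes(self) -> tuple[float, float]:
        """Semi-axes of the cavity surface (outer ellipse minus wall)."""
        a, b = self.outer_semi_axes
        return a - WALL_THICKNESS_MM, b - WALL_THICKNESS_MM

    @property
    def n_frames(self) -> int:
        return int(self.kick_duration_s / self.frame_interval_s) + 1

    def with_seed(self, seed: int) -> "KickScenario":
        return replace(self, rng_seed=int(seed))

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "KickScenario":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ParseError(f"invalid YAML in {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: expected a mapping of scenario fields")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(f"{path}: unknown scenario field(s) {sorted(unknown)}")
        missing = {
            "name", "gestational_age_weeks", "femur_length_mm", "tibia_length_mm",
            "uterus_major_axis_mm", "uterus_minor_axis_mm", "max_deflection_mm",
            "kick_duration_s",
        } - set(raw)
        if missing:
            raise ParseError(f"{path}: missing scenario field(s) {sorted(missing)}")
        return cls(**raw)


def default_cohort() -> list[KickScenario]:
    """The three study fetuses (A, B, C) with their measured geometry."""
    return [
        KickScenario(
            name="fetus_a", gestational_age_weeks=20,
            femur_length_mm=51.02, tibia_length_mm=54.58,
            uterus_major_axis_mm=160.12, uterus_minor_axis_mm=155.69,
            max_deflection_mm=6.40, kick_duration_s=3.0, rng_seed=101,
        ),
        KickScenario(
            name="fetus_b", gestational_age_weeks=21,
            femur_length_mm=58.34, tibia_length_mm=60.86,
            uterus_major_axis_mm=223.34, uterus_minor_axis_mm=156.88,
            max_deflection_mm=7.37, kick_duration_s=2.0, rng_seed=102,
        ),
        KickScenario(
            name="fetus_c", gestational_age_weeks=22,
            femur_length_mm=52.41, tibia_length_mm=59.81,
            uterus_major_axis_mm=185.09, uterus_minor_axis_mm=175.43,
            max_deflection_mm=7.07, kick_duration_s=3.3, rng_seed=103,
        ),
    ]
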