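"""Ground-truthed synthetic kick sequences emulating cine-MRI acquisitions.

The generator produces, for a :class:`~fetalkick.scenarios.KickScenario`,
(1) an exact per-frame trajectory of the hip, knee and ankle joints of a
planar leg performing an extension kick that brings the foot into sustained
contact with the uterine wall, and (2) rendered grayscale frames emulating
the appearance of a thick-slice cine acquisition: a bright elliptical wall
band (locally bulged outward under the kicking foot), bright bone capsules,
Gaussian joint blobs, Gaussian blur and additive Gaussian noise.

Coordinates are uterus-centred, in mm, x along the major axis.  Images are
row-major with pixel (i, j) centred at ``origin + (j, i) * pixel_size``
(``origin`` is the physical position of pixel (0, 0)'s centre).

The kick is parameterised by a cubic ease-in-out approach of the ankle
toward the wall along the contact normal followed by a smooth ramp of the
wall deflection up to the scenario's ``max_deflection_mm`` at the final
frame; the knee is placed by two-link inverse geometry so that the femur
and tibia lengths are conserved exactly at every frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError, ParseError
from .geometry import circle_circle_intersection, ellipse_outward_normal, ellipse_point
from .scenarios import KickScenario

TRUTH_COLUMNS = [
    "frame", "time_s", "hip_x", "hip_y", "knee_x", "knee_y",
    "ankle_x", "ankle_y", "contact", "deflection_mm",
]

# rendering intensities (fraction of dynamic range)
_WALL_INTENSITY = 0.45
_BONE_INTENSITY = 0.65
_BLOB_AMPLITUDE = 0.9  # joint blobs are the brightest landmarks
_BONE_RADIUS_MM = 3.0
_BLOB_SIGMA_MM = 2.5
_FRAME_MARGIN_MM = 8.0
_APPROACH_MM_PER_FRAME = 2.0  # caps pre-contact ankle speed (trackable regime)


@dataclass
class GroundTruthTrajectory:
    """Exact per-frame joint positions and wall deflection for one kick."""

    times: np.ndarray          # (n,) s
    hip: np.ndarray            # (n, 2) mm
    knee: np.ndarray           # (n, 2) mm
    ankle: np.ndarray          # (n, 2) mm
    contact: np.ndarray        # (n,) bool
    deflection: np.ndarray     # (n,) mm
    contact_point: np.ndarray  # (2,) mm, wall point of first contact
    contact_normal: np.ndarray  # (2,) unit outward wall normal at contact

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class ImageSequence:
    """Time-ordered 2D grayscale frames with physical pixel geometry."""

    frames: np.ndarray       # (n, H, W)
    pixel_size_mm: float
    frame_interval_s: float
    origin_mm: np.ndarray    # (2,) physical position of pixel (0,0) centre

    def __post_init__(self):
        if self.pixel_size_mm <= 0:
            raise ConfigurationError("pixel_size_mm must be > 0")
        if not np.all(np.isfinite(self.frames)):
            raise ConfigurationError("frames contain non-finite intensities")

    def mm_to_px(self, p_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(p_mm) - self.origin_mm) / self.pixel_size_mm

    def px_to_mm(self, p_px: np.ndarray) -> np.ndarray:
        return np.asarray(p_px) * self.pixel_size_mm + self.origin_mm


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Cubic ease-in-out on [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def generate_kick_kinematics(scenario: KickScenario) -> GroundTruthTrajectory:
    """Exact joint kinematics of a planar extension kick.

    The ankle approaches the cavity surface along the inward normal at the
    configured contact angle with a cubic ease-in-out profile, reaching the
    surface at the first contact frame, then pushes the wall outward along
    the same normal with a smooth ramp to ``max_deflection_mm`` at the last
    frame.  The hip performs a small bounded drift; the knee is solved from
    the two segment-length circles so both lengths hold exactly.
    """
    fem, tib = scenario.femur_length_mm, scenario.tibia_length_mm
    limb = fem + tib
    ai, bi = scenario.inner_semi_axes
    if ai <= 0 or bi <= 0:
        raise ConfigurationError("uterus too small for the wall thickness")
    dmax = scenario.max_deflection_mm

    contact_pt = ellipse_point(scenario.contact_theta, ai, bi)
    n_out = ellipse_outward_normal(scenario.contact_theta, ai, bi)

    # hip placed on the inward normal so the leg is nearly extended at contact
    hip_dist = min(0.97 * limb, 0.99 * limb - dmax)
    if hip_dist <= abs(fem - tib) * 1.02:
        raise ConfigurationError(
            "limb cannot reach the wall from the configured hip position "
            f"(hip-to-wall distance {hip_dist:.2f} mm, |femur-tibia| "
            f"{abs(fem - tib):.2f} mm)"
        )
    t_hat = np.array([-n_out[1], n_out[0]])
    hip0 = contact_pt - hip_dist * n_out \
        + scenario.hip_lateral_offset_mm * t_hat
    if (hip0[0] / ai) ** 2 + (hip0[1] / bi) ** 2 >= 0.9:
        raise ConfigurationError("hip position falls outside the uterine cavity")

    n = scenario.n_frames
    times = np.arange(n) * scenario.frame_interval_s
    k = int(round(scenario.contact_fraction * (n - 1)))
    k = min(max(k, 1), n - 2) if n > 2 else max(n - 1, 0)

    # ankle path: distance from the wall point (negative = short of the wall).
    # The approach amplitude is capped so peak inter-frame ankle displacement
    # stays near one pixel, consistent with the bounded inter-frame movement
    # the tracking stage assumes.
    k_contact = int(round(scenario.contact_fraction * (scenario.n_frames - 1)))
    approach = min(0.12 * limb, _APPROACH_MM_PER_FRAME * max(k_contact, 1))
    stop = 0.0 if dmax > 0 else scenario.pixel_size_mm
    s = np.empty(n)
    if k > 0:
        u = np.arange(k + 1) / k
        s[: k + 1] = -(approach - (approach - stop) * _smoothstep(u))
    if n - 1 > k:
        v = (np.arange(k, n) - k) / (n - 1 - k)
        s[k:] = dmax * _smoothstep(v) - stop
    deflection = np.clip(s, 0.0, None)
    ankle = contact_pt[None, :] + s[:, None] * n_out[None, :]

    # small smooth hip drift orthogonal to the kick direction
    t_perp = np.array([-n_out[1], n_out[0]])
    u_all = np.arange(n) / max(n - 1, 1)
    drift = scenario.hip_drift_mm * np.sin(np.pi * u_all)
    hip = hip0[None, :] + drift[:, None] * t_perp[None, :]

    knee = np.empty_like(ankle)
    for i in range(n):
        try:
            knee[i] = circle_circle_intersection(hip[i], fem, ankle[i], tib, side=+1)
        except ValueError as exc:
            raise ConfigurationError(f"knee placement failed at frame {i}: {exc}")

    contact = s >= -0.5 * scenario.pixel_size_mm if dmax > 0 else np.zeros(n, bool)
    deflection = np.where(contact, deflection, 0.0)
    return GroundTruthTrajectory(
        times=times, hip=hip, knee=knee, ankle=ankle,
        contact=contact, deflection=deflection,
        contact_point=contact_pt, contact_normal=n_out,
    )


def render_frames(truth: GroundTruthTrajectory, scenario: KickScenario) -> ImageSequence:
    """Rasterize a ground-truth trajectory into a noisy grayscale sequence."""
    p = scenario.pixel_size_mm
    if p <= 0:
        raise ConfigurationError("pixel_size_mm must be > 0")
    ao, bo = scenario.outer_semi_axes
    ai, bi = scenario.inner_semi_axes
    half_x = ao + _FRAME_MARGIN_MM
    half_y = bo + _FRAME_MARGIN_MM
    W = int(np.ceil(2 * half_x / p))
    H = int(np.ceil(2 * half_y / p))
    origin = np.array([-half_x + 0.5 * p, -half_y + 0.5 * p])
    xs = origin[0] + np.arange(W) * p
    ys = origin[1] + np.arange(H) * p
    X, Y = np.meshgrid(xs, ys)

    bump_halfwidth = 7.5  # mm; visual half-width of the wall bulge
    rng = np.random.default_rng(scenario.rng_seed)
    frames = np.empty((truth.n_frames, H, W), dtype=np.float64)

    for i in range(truth.n_frames):
        img = np.zeros((H, W))
        # wall band, sampled at positions pulled back by the local bulge
        d = truth.deflection[i]
        if d > 0:
            cx, cy = truth.contact_point
            g = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * bump_halfwidth**2))
            Xs = X - d * g * truth.contact_normal[0]
            Ys = Y - d * g * truth.contact_normal[1]
        else:
            Xs, Ys = X, Y
        img = _WALL_INTENSITY * _soft_band(Xs, Ys, ao, bo, ai, bi)

        for a, b in ((truth.hip[i], truth.knee[i]), (truth.knee[i], truth.ankle[i])):
            img = np.maximum(img, _BONE_INTENSITY * _capsule_mask(X, Y, a, b))
        for joint in (truth.hip[i], truth.knee[i], truth.ankle[i]):
            r2 = (X - joint[0]) ** 2 + (Y - joint[1]) ** 2
            img += _BLOB_AMPLITUDE * np.exp(-r2 / (2 * _BLOB_SIGMA_MM**2))

        if scenario.blur_sigma_mm > 0:
            img = ndimage.gaussian_filter(img, scenario.blur_sigma_mm / p)
        frames[i] = img

    dyn_range = float(frames.max() - frames.min())
    if scenario.noise_sd > 0:
        frames = frames + rng.normal(
            0.0, scenario.noise_sd * dyn_range, size=frames.shape
        )
    return ImageSequence(
        frames=frames, pixel_size_mm=p,
        frame_interval_s=scenario.frame_interval_s, origin_mm=origin,
    )


_EDGE_WIDTH_MM = 0.6  # soft (antialiased) edge width of rendered structures


def _soft_edge(signed_distance_mm: np.ndarray) -> np.ndarray:
    """Smooth 1 -> 0 transition across an edge (positive = inside)."""
    return 1.0 / (1.0 + np.exp(-signed_distance_mm / (0.5 * _EDGE_WIDTH_MM)))


def _soft_band(X, Y, ao, bo, ai, bi) -> np.ndarray:
    """Soft-edged elliptical wall band between the cavity and outer surface.

    Signed distances are approximated from the normalized elliptical radius
    scaled by the local radius, which is accurate to well below the edge
    width for the mild eccentricities used here.
    """
    r = np.sqrt(X * X + Y * Y) + 1e-9
    q_out = np.sqrt((X / ao) ** 2 + (Y / bo) ** 2)
    q_in = np.sqrt((X / ai) ** 2 + (Y / bi) ** 2)
    d_out = (1.0 - q_out) * r / np.maximum(q_out, 1e-9)
    d_in = (q_in - 1.0) * r / np.maximum(q_in, 1e-9)
    return _soft_edge(d_out) * _soft_edge(d_in)


def _capsule_mask(X, Y, a, b) -> np.ndarray:
    """Intensity profile (0..1) of the ossified shaft of segment a-b.

    Soft-edged radially (antialiased), and fading toward both ends over
    the outer quarter of the segment (the cartilaginous epiphyses carry
    little shaft signal), which keeps the joint neighbourhoods dominated
    by the joint blobs.
    """
    ab = b - a
    L2 = float(ab @ ab)
    t = np.clip(((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / L2, 0.0, 1.0)
    dx = X - (a[0] + t * ab[0])
    dy = Y - (a[1] + t * ab[1])
    radial = _soft_edge(_BONE_RADIUS_MM - np.sqrt(dx * dx + dy * dy))
    taper = _smoothstep(np.minimum(t, 1.0 - t) / 0.25)
    return radial * taper


def generate_sequence(scenario: KickScenario):
    """Convenience: kinematics + rendering in one call."""
    truth = generate_kick_kinematics(scenario)
    return truth, render_frames(truth, scenario)


# ---------------------------------------------------------------------------
# fixture I/O


def write_fixture(truth: GroundTruthTrajectory, sequence: ImageSequence,
                  path, backend: str = "tiff") -> None:
    """Write a lossless fixture: truth CSV + frame stack + metadata JSON."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "frame": np.arange(truth.n_frames),
        "time_s": truth.times,
        "hip_x": truth.hip[:, 0], "hip_y": truth.hip[:, 1],
        "knee_x": truth.knee[:, 0], "knee_y": truth.knee[:, 1],
        "ankle_x": truth.ankle[:, 0], "ankle_y": truth.ankle[:, 1],
        "contact": truth.contact.astype(int),
        "deflection_mm": truth.deflection,
    })
    df.to_csv(path / "truth.csv", index=False, float_format="%.17g")
    frames32 = sequence.frames.astype(np.float32)
    if backend == "tiff":
        import tifffile
        tifffile.imwrite(path / "frames.tif", frames32)
    elif backend == "nifti":
        import nibabel as nib
        affine = np.diag([sequence.pixel_size_mm, sequence.pixel_size_mm, 1.0, 1.0])
        nib.save(nib.Nifti1Image(frames32.transpose(2, 1, 0), affine),
                 path / "frames.nii.gz")
    else:
        raise ValueError(f"unknown backend '{backend}'")
    meta = {
        "backend": backend,
        "pixel_size_mm": sequence.pixel_size_mm,
        "frame_interval_s": sequence.frame_interval_s,
        "origin_mm": list(map(float, sequence.origin_mm)),
        "contact_point_mm": list(map(float, truth.contact_point)),
        "contact_normal": list(map(float, truth.contact_normal)),
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def read_fixture(path):
    """Read a fixture written by :func:`write_fixture`."""
    path = Path(path)
    meta_file = path / "meta.json"
    if not meta_file.exists():
        raise ParseError(f"missing metadata file {meta_file}")
    meta = json.loads(meta_file.read_text())
    for field in ("backend", "pixel_size_mm", "frame_interval_s", "origin_mm"):
        if field not in meta:
            raise ParseError(f"{meta_file}: missing field '{field}'")

    try:
        df = pd.read_csv(path / "truth.csv")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"unreadable truth CSV: {exc}") from exc
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"truth.csv: missing column(s) {sorted(missing)}")
    if df[TRUTH_COLUMNS].isna().any().any():
        bad = [c for c in TRUTH_COLUMNS if df[c].isna().any()]
        raise ParseError(f"truth.csv: non-numeric or missing values in {bad}")

    truth = GroundTruthTrajectory(
        times=df["time_s"].to_numpy(),
        hip=df[["hip_x", "hip_y"]].to_numpy(),
        knee=df[["knee_x", "knee_y"]].to_numpy(),
        ankle=df[["ankle_x", "ankle_y"]].to_numpy(),
        contact=df["contact"].to_numpy().astype(bool),
        deflection=df["deflection_mm"].to_numpy(),
        contact_point=np.array(meta.get("contact_point_mm", [np.nan, np.nan])),
        contact_normal=np.array(meta.get("contact_normal", [np.nan, np.nan])),
    )
    if meta["backend"] == "tiff":
        import tifffile
        frames = tifffile.imread(path / "frames.tif")
    elif meta["backend"] == "nifti":
        import nibabel as nib
        frames = np.asarray(
            nib.load(path / "frames.nii.gz").dataobj, dtype=np.float32
        ).transpose(2, 1, 0)
    else:
        raise ParseError(f"{meta_file}: unknown backend '{meta['backend']}'")
    sequence = ImageSequence(
        frames=np.asarray(frames, dtype=np.float32),
        pixel_size_mm=float(meta["pixel_size_mm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        origin_mm=np.array(meta["origin_mm"], dtype=float),
    )
    return truth, sequence
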