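"""Accumulated weighted template matching with kinematic constraints.

The tracker follows the hip, knee and ankle through a grayscale sequence.
On each frame the hip is located first by maximizing a recency-weighted
average of zero-normalized cross-correlations (ZNCC) against the templates
accumulated from all previous frames.  Knee candidates are then restricted
to positions that both lie within the per-frame search radius and keep the
hip-knee distance within a +/-10% band of the running femur length; the
ankle is found the same way against the running tibia length.  Uterine-wall
deflection is the translational displacement of the ankle from its position
at first wall contact, over the frames in contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigurationError, DegenerateMatchError, TrackLostError
from .geometry import signed_distance_to_ellipse
from .synthetic_cine import ImageSequence


@dataclass
class TrackingConfig:
    # template pyramid: centre-weighted ZNCC maps from each half-width are
    # averaged; the small scale limits appearance-change bias, the larger
    # one suppresses noise
    template_halfwidths: tuple = (2, 3)
    scale_weights: tuple = (0.6, 0.4)      # fine scale weighted higher
    template_halfwidth: int | None = None  # set to force a single scale
    search_radius: int = 3           # px; max inter-frame joint motion
    knee_search_radius: int = 5      # px; the knee sweeps fastest mid-kick
    length_tolerance: float = 0.10   # allowed fractional segment-length change
    recency_decay: float = 0.8       # per-frame geometric weight decay
    min_match_score: float = 0.30    # reject matches below this correlation
    length_ema_alpha: float = 0.30   # running-length update rate
    max_templates: int = 12          # oldest templates dropped beyond this
    presmooth_sigma: float = 0.0     # px; optional smoothing before ZNCC
    min_update_score: float = 0.60   # only matches at least this good refresh templates

    def __post_init__(self):
        if self.template_halfwidth is not None:
            self.template_halfwidths = (self.template_halfwidth,)
        if len(self.scale_weights) < len(self.template_halfwidths):
            raise ConfigurationError("need a scale weight per half-width")
        if not 0.0 < self.length_tolerance < 1.0:
            raise ConfigurationError("length_tolerance must be in (0, 1)")
        if min(self.template_halfwidths) < 1 or self.search_radius < 1:
            raise ConfigurationError(
                "template half-widths and search_radius must be >= 1"
            )
        if not 0.0 < self.recency_decay <= 1.0:
            raise ConfigurationError("recency_decay must be in (0, 1]")


class TemplateEnsemble:
    """Templates accumulated over frames with geometric recency weights."""

    def __init__(self, decay: float, max_templates: int = 12):
        self.decay = decay
        self.max_templates = max_templates
        self.patches: list[np.ndarray] = []

    def add(self, patch: np.ndarray) -> None:
        self.patches.append(np.asarray(patch, dtype=float))
        if len(self.patches) > self.max_templates:
            self.patches.pop(0)

    @property
    def weights(self) -> np.ndarray:
        """Normalized weights; the most recent template weighs the most."""
        ages = np.arange(len(self.patches))[::-1]
        w = self.decay**ages
        return w / w.sum()


def _taper(shape: tuple[int, int]) -> np.ndarray:
    """Gaussian window emphasizing the patch centre (normalized to sum 1)."""
    h = (shape[0] - 1) // 2
    y, x = np.mgrid[-h : h + 1, -h : h + 1]
    g = np.exp(-(x * x + y * y) / (2.0 * max(h, 1) ** 2))
    return g / g.sum()


def _zncc_map(windows: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Centre-weighted ZNCC of a stack of windows against one template.

    A Gaussian taper weights the correlation toward the patch centre so
    that the tracked landmark, not high-contrast structure at the patch
    periphery, dominates the match.
    """
    g = _taper(template.shape)
    t = template - (g * template).sum()
    t_norm = np.sqrt((g * t * t).sum())
    if template.std() == 0.0:
        raise DegenerateMatchError("template has zero intensity variance")
    wmean = np.einsum("...ij,ij->...", windows, g)[..., None, None]
    w = windows - wmean
    w_norm = np.sqrt(np.einsum("...ij,ij->...", w * w, g))
    num = np.einsum("...ij,ij->...", w, g * t)
    out = np.zeros(num.shape)
    ok = (w_norm > 0) & (t_norm > 0)
    out[ok] = num[ok] / (w_norm[ok] * t_norm)
    return out


def ncc_match(frame: np.ndarray, ensemble: TemplateEnsemble, region):
    """Best weighted-ZNCC position of the ensemble within a pixel rectangle.

    ``region`` is (x0, x1, y0, y1): inclusive bounds of candidate template
    *centres*.  Returns ((x, y), score); the score is the weight-averaged
    ZNCC in [-1, 1].  Ties resolve to the smallest row-major index.
    """
    pos, score, _ = _match_region(frame, ensemble, region)
    return pos, score


def _match_region(frame: np.ndarray, ensemble: TemplateEnsemble, region):
    if not ensemble.patches:
        raise DegenerateMatchError("empty template ensemble")
    h = (ensemble.patches[0].shape[0] - 1) // 2
    x0, x1, y0, y1 = region
    H, W = frame.shape
    if not (0 <= x0 <= x1 < W and 0 <= y0 <= y1 < H):
        raise ConfigurationError(f"match region {region} outside frame {frame.shape}")
    padded = np.pad(frame, h, mode="reflect")
    # window with centre (x, y) is padded[y : y+2h+1, x : x+2h+1]
    sub = padded[y0 : y1 + 2 * h + 1, x0 : x1 + 2 * h + 1]
    windows = sliding_window_view(sub, (2 * h + 1, 2 * h + 1))
    if np.all(windows.std(axis=(-2, -1)) == 0.0):
        raise DegenerateMatchError("search region has zero intensity variance")
    combined = np.zeros(windows.shape[:2])
    for patch, weight in zip(ensemble.patches, ensemble.weights):
        combined += weight * _zncc_map(windows, patch)
    idx = np.unravel_index(np.argmax(combined), combined.shape)
    pos = (x0 + idx[1], y0 + idx[0])
    return pos, float(combined[idx]), combined


def _subpixel_offset(m: np.ndarray, iy: int, ix: int) -> np.ndarray:
    """Quadratic (3-point parabola) refinement of a score-map peak."""
    out = np.zeros(2)
    if 0 < ix < m.shape[1] - 1:
        l, c, r = m[iy, ix - 1], m[iy, ix], m[iy, ix + 1]
        den = l + r - 2 * c
        if den < 0:
            out[0] = np.clip(0.5 * (l - r) / den, -0.5, 0.5)
    if 0 < iy < m.shape[0] - 1:
        l, c, r = m[iy - 1, ix], m[iy, ix], m[iy + 1, ix]
        den = l + r - 2 * c
        if den < 0:
            out[1] = np.clip(0.5 * (l - r) / den, -0.5, 0.5)
    return out


def _extract_patch(frame: np.ndarray, pos, halfwidth: int) -> np.ndarray:
    """Landmark-centred patch, bilinearly sampled at a sub-pixel position."""
    h = halfwidth
    x, y = float(pos[0]), float(pos[1])
    if x == round(x) and y == round(y):
        padded = np.pad(frame, h, mode="reflect")
        return padded[int(y) : int(y) + 2 * h + 1, int(x) : int(x) + 2 * h + 1].copy()
    from scipy.ndimage import map_coordinates
    dy, dx = np.mgrid[-h : h + 1, -h : h + 1].astype(float)
    return map_coordinates(frame, [dy + y, dx + x], order=1, mode="reflect")


@dataclass
class JointTrajectory:
    """Per-frame positions of one joint in pixels and mm."""

    name: str
    px: np.ndarray              # (n, 2) pixel coordinates (x, y)
    pixel_size_mm: float
    origin_mm: np.ndarray       # (2,)
    score: np.ndarray           # (n,)
    valid: np.ndarray           # (n,) bool

    @property
    def mm(self) -> np.ndarray:
        return self.px * self.pixel_size_mm + self.origin_mm

    def __len__(self) -> int:
        return len(self.px)


@dataclass
class DeflectionResult:
    """Contact window and wall deflection derived from the ankle track."""

    window: tuple[int, int] | None   # inclusive frame range, None if no contact
    max_displacement_mm: float
    displacement_mm: np.ndarray      # (n,) per-frame, 0 outside the window


@dataclass
class SummaryStat:
    mean: float
    spread: float  # population standard deviation (divisor n)


@dataclass
class _TrackerState:
    config: TrackingConfig
    pixel_size_mm: float
    ensembles: dict = field(default_factory=dict)
    positions: dict = field(default_factory=dict)   # joint -> list of (x, y)
    scores: dict = field(default_factory=dict)
    femur_mm: float = 0.0
    tibia_mm: float = 0.0
    frame_index: int = 0


def _init_state(frame0: np.ndarray, seeds, config: TrackingConfig,
                pixel_size_mm: float) -> _TrackerState:
    H, W = frame0.shape
    joints = ("hip", "knee", "ankle")
    for name, (x, y) in zip(joints, seeds):
        if not (0 <= x < W and 0 <= y < H):
            raise ConfigurationError(
                f"seed for {name} at ({x}, {y}) outside frame of shape {frame0.shape}"
            )
    state = _TrackerState(config=config, pixel_size_mm=pixel_size_mm)
    for name, seed in zip(joints, seeds):
        scales = []
        for h in config.template_halfwidths:
            ens = TemplateEnsemble(config.recency_decay, config.max_templates)
            ens.add(_extract_patch(frame0, seed, h))
            scales.append(ens)
        state.ensembles[name] = scales
        state.positions[name] = [np.asarray(seed, dtype=float)]
        state.scores[name] = [1.0]
    p = pixel_size_mm
    state.femur_mm = float(
        np.linalg.norm(np.subtract(seeds[1], seeds[0])) * p
    )
    state.tibia_mm = float(
        np.linalg.norm(np.subtract(seeds[2], seeds[1])) * p
    )
    return state


def _admissible_best(frame, ensemble, centre, state, length_anchor=None,
                     running_length=None, joint="?"):
    """Best-scoring candidate within the search disc (and length annulus)."""
    cfg = state.config
    r = cfg.knee_search_radius if joint == "knee" else cfg.search_radius
    H, W = frame.shape
    cx, cy = int(round(centre[0])), int(round(centre[1]))
    x0, x1 = max(cx - r, 0), min(cx + r, W - 1)
    y0, y1 = max(cy - r, 0), min(cy + r, H - 1)
    w = np.asarray(cfg.scale_weights[: len(ensemble)], dtype=float)
    w = w / w.sum()
    scores = sum(
        wi * _match_region(frame, ens, (x0, x1, y0, y1))[2]
        for wi, ens in zip(w, ensemble)
    )

    gx, gy = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    ok = (gx - centre[0]) ** 2 + (gy - centre[1]) ** 2 <= r * r
    if length_anchor is not None:
        dist_mm = np.hypot(gx - length_anchor[0], gy - length_anchor[1]) \
            * state.pixel_size_mm
        lo = running_length * (1.0 - cfg.length_tolerance)
        hi = running_length * (1.0 + cfg.length_tolerance)
        ok &= (dist_mm >= lo) & (dist_mm <= hi)
    masked = np.where(ok, scores, -np.inf)
    idx = np.unravel_index(np.argmax(masked), masked.shape)
    best = masked[idx]
    if not np.isfinite(best) or best < cfg.min_match_score:
        raise TrackLostError(joint, state.frame_index,
                             f"best admissible score {best:.3f} below "
                             f"threshold {cfg.min_match_score}")
    # sub-pixel refinement of the peak (admissibility decided on the grid)
    offset = _subpixel_offset(scores, idx[0], idx[1])
    return np.array([gx[idx] + offset[0], gy[idx] + offset[1]]), float(best)


def track_frame(state: _TrackerState, frame: np.ndarray) -> _TrackerState:
    """Advance the tracker by one frame (hip, then knee, then ankle)."""
    cfg = state.config
    state.frame_index += 1
    hip, s_hip = _admissible_best(
        frame, state.ensembles["hip"], state.positions["hip"][-1], state,
        joint="hip",
    )
    knee, s_knee = _admissible_best(
        frame, state.ensembles["knee"], state.positions["knee"][-1], state,
        length_anchor=hip, running_length=state.femur_mm, joint="knee",
    )
    ankle, s_ankle = _admissible_best(
        frame, state.ensembles["ankle"], state.positions["ankle"][-1], state,
        length_anchor=knee, running_length=state.tibia_mm, joint="ankle",
    )
    for name, pos, score in (
        ("hip", hip, s_hip), ("knee", knee, s_knee), ("ankle", ankle, s_ankle)
    ):
        state.positions[name].append(pos)
        state.scores[name].append(score)
        # poor matches are kept as positions but do not refresh the
        # ensembles, so one bad frame cannot corrupt the templates
        if score >= cfg.min_update_score:
            for h, ens in zip(cfg.template_halfwidths, state.ensembles[name]):
                ens.add(_extract_patch(frame, pos, h))
    a = cfg.length_ema_alpha
    p = state.pixel_size_mm
    state.femur_mm = (1 - a) * state.femur_mm + a * float(
        np.linalg.norm(knee - hip) * p
    )
    state.tibia_mm = (1 - a) * state.tibia_mm + a * float(
        np.linalg.norm(ankle - knee) * p
    )
    return state


def track_sequence(sequence: ImageSequence, seeds,
                   config: TrackingConfig | None = None):
    """Track hip, knee and ankle through a whole sequence.

    ``seeds`` are three (x, y) pixel positions on frame 0 (hip, knee,
    ankle).  Returns three :class:`JointTrajectory`.  Deterministic: the
    template ensembles accumulate in frame order with fixed weights.
    """
    config = config or TrackingConfig()
    frames = np.asarray(sequence.frames, dtype=float)
    if config.presmooth_sigma > 0:
        from scipy.ndimage import gaussian_filter
        frames = np.stack(
            [gaussian_filter(f, config.presmooth_sigma) for f in frames]
        )
    state = _init_state(frames[0], seeds, config, sequence.pixel_size_mm)
    for frame in frames[1:]:
        state = track_frame(state, frame)
    out = []
    for name in ("hip", "knee", "ankle"):
        px = np.asarray(state.positions[name])
        out.append(JointTrajectory(
            name=name, px=px, pixel_size_mm=sequence.pixel_size_mm,
            origin_mm=np.asarray(sequence.origin_mm, dtype=float),
            score=np.asarray(state.scores[name]),
            valid=np.ones(len(px), dtype=bool),
        ))
    return tuple(out)


def segment_lengths(hip: JointTrajectory, knee: JointTrajectory,
                    ankle: JointTrajectory) -> tuple[float, float]:
    """Per-frame mean femur (hip-knee) and tibia (knee-ankle) lengths, mm."""
    if not (len(hip) == len(knee) == len(ankle)):
        raise ConfigurationError("trajectories have mismatched lengths")
    femur = float(np.linalg.norm(knee.mm - hip.mm, axis=1).mean())
    tibia = float(np.linalg.norm(ankle.mm - knee.mm, axis=1).mean())
    return femur, tibia


def wall_deflection(ankle: JointTrajectory, inner_semi_axes,
                    contact_band_mm: float | None = None) -> DeflectionResult:
    """Wall deflection from the ankle track against the cavity ellipse.

    A frame is in contact when the ankle lies within ``contact_band_mm``
    (default half a pixel) of the cavity surface or beyond it.  The
    deflection is the Euclidean displacement of the ankle from its position
    at first contact; the maximum is taken over the contact window.
    """
    a, b = inner_semi_axes
    if a <= 0 or b <= 0:
        raise ConfigurationError("inner ellipse semi-axes must be positive")
    if contact_band_mm is None:
        contact_band_mm = 0.5 * ankle.pixel_size_mm
    mm = ankle.mm
    sd = np.array([signed_distance_to_ellipse(p, a, b) for p in mm])
    in_contact = sd >= -contact_band_mm
    n = len(mm)
    displacement = np.zeros(n)
    if not in_contact.any():
        return DeflectionResult(window=None, max_displacement_mm=0.0,
                                displacement_mm=displacement)
    first = int(np.argmax(in_contact))
    last = int(n - 1 - np.argmax(in_contact[::-1]))
    ref = mm[first]
    idx = np.arange(first, last + 1)
    displacement[idx] = np.linalg.norm(mm[idx] - ref, axis=1)
    return DeflectionResult(
        window=(first, last),
        max_displacement_mm=float(displacement[idx].max()),
        displacement_mm=displacement,
    )


def summarize(values) -> SummaryStat:
    """Mean and population standard deviation (divisor n)."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ConfigurationError("cannot summarize an empty list")
    return SummaryStat(mean=float(values.mean()),
                       spread=float(values.std(ddof=0)))


def seeds_from_truth(truth, sequence: ImageSequence):
    """Integer pixel seeds for frame 0 from a ground-truth trajectory."""
    return [
        tuple(int(round(c)) for c in sequence.mm_to_px(p))
        for p in (truth.hip[0], truth.knee[0], truth.ankle[0])
    ]
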