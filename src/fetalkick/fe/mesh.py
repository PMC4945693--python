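"""Mesh construction for the uterine-wall indentation models.

Geometry enters in mm (matching the imaging stages) and is converted to
metres internally; forces are per metre of out-of-plane depth unless a
different thickness is configured.

The wall is a half-ellipse bilayer ring (thin fetal membrane lining the
cavity plus the uterine muscle layer) meshed with radially conforming
bilinear quads, graded circumferentially toward the contact site.  The
cartilage probe standing in for the fetal foot is a round-ended block
meshed by transfinite interpolation, its tip arc facing the cavity surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import ConfigurationError, MeshError
from ..geometry import ellipse_outward_normal, ellipse_point
from . import elements

MM = 1e-3


@dataclass(frozen=True)
class Material:
    """Linear elastic isotropic material."""

    elastic_modulus: float   # Pa
    poisson_ratio: float

    def __post_init__(self):
        if self.elastic_modulus <= 0:
            raise ConfigurationError("elastic_modulus must be > 0")
        if not 0.0 <= self.poisson_ratio < 0.5:
            raise ConfigurationError("poisson_ratio must be in [0, 0.5)")


# material constants for the uterine environment
MEMBRANE = Material(7.53e6, 0.40)        # fetal membrane
UTERINE_MUSCLE = Material(0.586e6, 0.40)  # pregnant uterine muscle
CARTILAGE_PROBE = Material(1.1e6, 0.49)   # fetal cartilage


@dataclass(frozen=True)
class UterusGeometry:
    """Half-ellipse bilayer wall indented by a round-ended probe."""

    major_axis_mm: float             # outer wall ellipse, full axis
    minor_axis_mm: float
    membrane_thickness_mm: float = 0.6
    muscle_thickness_mm: float = 6.0
    probe_width_mm: float = 15.0     # foot-sized probe diameter
    # contact at the arc midpoint of the half model (the minor-axis apex),
    # farthest from both cut boundaries and symmetric about the load
    contact_theta: float = np.pi / 2

    def __post_init__(self):
        if self.membrane_thickness_mm <= 0 or self.muscle_thickness_mm <= 0:
            raise ConfigurationError("layer thicknesses must be > 0")
        if self.probe_width_mm <= 0:
            raise ConfigurationError("probe_width_mm must be > 0")
        wall = self.membrane_thickness_mm + self.muscle_thickness_mm
        if min(self.major_axis_mm, self.minor_axis_mm) <= 2 * wall:
            raise ConfigurationError("ellipse axes must exceed twice the wall")

    @property
    def wall_thickness_mm(self) -> float:
        return self.membrane_thickness_mm + self.muscle_thickness_mm


@dataclass
class FEMesh:
    """Nodes, quad connectivity, region tags and boundary node sets."""

    nodes: np.ndarray                  # (N, 2) metres, reference config
    elems: np.ndarray                  # (E, 4) int, counter-clockwise
    regions: np.ndarray                # (E,) str tags
    out_of_plane_thickness: float = 1.0  # metres
    node_sets: dict = field(default_factory=dict)
    # contact surfaces: ordered node chains (indices into nodes)
    master_chain: np.ndarray | None = None   # wall cavity surface
    slave_nodes: np.ndarray | None = None    # probe tip nodes

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    def check_jacobians(self) -> None:
        det = elements.jacobians(self.nodes[self.elems])
        if np.any(det <= 0):
            bad = int(np.argwhere(np.any(det <= 0, axis=1))[0, 0])
            raise MeshError(f"inverted element {bad}")


def _structured_quads(ni: int, nj: int) -> np.ndarray:
    """Connectivity of an ni x nj structured grid of quads."""
    idx = np.arange((ni + 1) * (nj + 1)).reshape(ni + 1, nj + 1)
    e = np.stack([
        idx[:-1, :-1], idx[1:, :-1], idx[1:, 1:], idx[:-1, 1:]
    ], axis=-1)
    return e.reshape(-1, 4)


def _orient_ccw(nodes: np.ndarray, elems: np.ndarray) -> np.ndarray:
    """Flip element node order where the mapping is left-handed."""
    det = elements.jacobians(nodes[elems])
    flip = det.min(axis=1) <= 0
    elems = elems.copy()
    elems[flip] = elems[flip][:, ::-1]
    return elems


def _graded_thetas(theta_contact: float, size_near_mm: float,
                   size_far_mm: float, mean_radius_mm: float) -> np.ndarray:
    """Circumferential stations on [0, pi], refined near the contact angle.

    Stations march outward from the contact angle so the mesh is mirror
    symmetric about it whenever the geometry is.
    """
    spread = 0.45  # radians over which the grading relaxes

    def size(theta):
        t = min(abs(theta - theta_contact) / spread, 1.0)
        return size_near_mm + (size_far_mm - size_near_mm) * t

    def march(stop):
        out = [theta_contact]
        direction = 1.0 if stop > theta_contact else -1.0
        while (stop - out[-1]) * direction > 0:
            out.append(out[-1] + direction * size(out[-1]) / mean_radius_mm)
        t = np.array(out)
        # stretch this side so its last station lands exactly on the end
        return theta_contact + (t - theta_contact) * (
            (stop - theta_contact) / (t[-1] - theta_contact)
        )

    left = march(0.0)[::-1]
    right = march(np.pi)
    return np.concatenate([left, right[1:]])


def build_wall_mesh(geom: UterusGeometry, n_membrane: int = 2,
                    n_muscle: int = 6, size_near_mm: float = 2.0,
                    size_far_mm: float = 8.0) -> FEMesh:
    """Half-ellipse bilayer wall (theta in [0, pi], cut on the major axis)."""
    if n_membrane < 2 or n_muscle < 4:
        raise MeshError(
            "resolution too coarse: need >= 2 elements through the membrane "
            "and >= 4 through the muscle"
        )
    ao, bo = geom.major_axis_mm / 2.0, geom.minor_axis_mm / 2.0
    wall = geom.wall_thickness_mm
    ai, bi = ao - wall, bo - wall
    if ai <= 0 or bi <= 0:
        raise ConfigurationError("wall thicker than the ellipse semi-axes")

    mean_radius = 0.25 * (ao + bo + ai + bi)
    thetas = _graded_thetas(geom.contact_theta, size_near_mm, size_far_mm,
                            mean_radius)
    # through-thickness stations: 0 at cavity surface -> 1 at outer surface
    f_mem = np.linspace(0.0, geom.membrane_thickness_mm / wall, n_membrane + 1)
    f_mus = np.linspace(geom.membrane_thickness_mm / wall, 1.0, n_muscle + 1)
    fracs = np.concatenate([f_mem, f_mus[1:]])

    inner = ellipse_point(thetas, ai, bi)
    outer = ellipse_point(thetas, ao, bo)
    # nodes indexed [i_theta, j_frac]
    nodes = (inner[:, None, :]
             + fracs[None, :, None] * (outer - inner)[:, None, :]) * MM
    ni, nj = len(thetas) - 1, len(fracs) - 1
    nodes = nodes.reshape(-1, 2)
    elems = _orient_ccw(nodes, _structured_quads(ni, nj))

    regions = np.empty(ni * nj, dtype=object)
    layer = np.tile(np.arange(nj), ni)
    regions[layer < n_membrane] = "membrane"
    regions[layer >= n_membrane] = "muscle"

    idx = np.arange((ni + 1) * (nj + 1)).reshape(ni + 1, nj + 1)
    node_sets = {
        "cut_near": idx[0, :],      # theta = 0 cross-section (y = 0)
        "cut_far": idx[-1, :],      # theta = pi cross-section (y = 0)
        "cavity_surface": idx[:, 0],
        "outer_surface": idx[:, -1],
    }
    mesh = FEMesh(nodes=nodes, elems=elems, regions=regions.astype(str),
                  node_sets=node_sets, master_chain=idx[:, 0].copy())
    mesh.check_jacobians()
    # symmetry-plane nodes must sit on y = 0 exactly
    for s in ("cut_near", "cut_far"):
        assert np.all(np.abs(mesh.nodes[mesh.node_sets[s], 1]) < 1e-12)
    return mesh


def build_probe_mesh(tip_point_mm: np.ndarray, outward_normal: np.ndarray,
                     width_mm: float, n_across: int = 8,
                     n_axial: int = 4, shaft_mm: float | None = None):
    """Round-ended probe, tip apex at ``tip_point_mm`` facing ``outward_normal``.

    The probe lies inside the cavity with its axis along the outward wall
    normal; the tip is a semicircular arc of radius width/2, blended by
    transfinite interpolation to a flat rear (control) face.
    Returns (nodes_m, elems, tip_chain, control_nodes).
    """
    R = width_mm / 2.0
    if shaft_mm is None:
        shaft_mm = 0.8 * R
    n = np.asarray(outward_normal, dtype=float)
    n = n / np.linalg.norm(n)
    t = np.array([-n[1], n[0]])
    tip = np.asarray(tip_point_mm, dtype=float)
    centre = tip - R * n                      # centre of the tip arc
    rear_c = centre - shaft_mm * n

    xi = np.linspace(-1.0, 1.0, n_across + 1)
    zeta = np.linspace(0.0, 1.0, n_axial + 1)
    phi = xi * (np.pi / 2.0)
    arc = centre[None, :] + R * (np.cos(phi)[:, None] * n[None, :]
                                 + np.sin(phi)[:, None] * t[None, :])
    rear = rear_c[None, :] + (xi * R)[:, None] * t[None, :]
    nodes = ((1.0 - zeta[None, :, None]) * arc[:, None, :]
             + zeta[None, :, None] * rear[:, None, :]) * MM

    ni, nj = n_across, n_axial
    nodes = nodes.reshape(-1, 2)
    elems = _orient_ccw(nodes, _structured_quads(ni, nj))
    idx = np.arange((ni + 1) * (nj + 1)).reshape(ni + 1, nj + 1)
    tip_chain = idx[:, 0].copy()
    control = idx[:, -1].copy()
    return nodes, elems, tip_chain, control


def merge_meshes(wall: FEMesh, probe_nodes: np.ndarray, probe_elems: np.ndarray,
                 tip_chain: np.ndarray, control: np.ndarray) -> FEMesh:
    """Wall and probe in one mesh (no shared nodes; contact couples them)."""
    offset = wall.n_nodes
    nodes = np.vstack([wall.nodes, probe_nodes])
    elems = np.vstack([wall.elems, probe_elems + offset])
    regions = np.concatenate([
        wall.regions, np.full(len(probe_elems), "probe", dtype=object)
    ]).astype(str)
    node_sets = dict(wall.node_sets)
    node_sets["probe_control"] = control + offset
    node_sets["probe_tip"] = tip_chain + offset
    mesh = FEMesh(nodes=nodes, elems=elems, regions=regions,
                  node_sets=node_sets,
                  master_chain=wall.master_chain,
                  slave_nodes=tip_chain + offset)
    mesh.check_jacobians()
    return mesh
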