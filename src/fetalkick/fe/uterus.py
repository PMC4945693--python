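"""Uterine-wall indentation models: build, solve, report, sensitivity.

The model follows the imaging-derived geometry: a half-ellipse bilayer wall
(fetal membrane lining the cavity, uterine muscle outside), indented from
inside by a round-ended cartilage probe of foot diameter at the quarter-arc
midpoint of the half model.  Both major-axis cut cross-sections are fully
restrained: with in-plane-free cuts the single oblique probe load excites
a soft global bending mode of the open ring instead of the local wall
indentation the measurement describes.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from ..geometry import ellipse_outward_normal, ellipse_point
from .mesh import (CARTILAGE_PROBE, MEMBRANE, MM, UTERINE_MUSCLE, FEMesh,
                   Material, UterusGeometry, build_probe_mesh, build_wall_mesh,
                   merge_meshes)
from .solver import BoundaryConditions, FEModel, FESolution, solve


def default_materials() -> dict:
    return {
        "membrane": MEMBRANE,
        "muscle": UTERINE_MUSCLE,
        "probe": CARTILAGE_PROBE,
    }


def build_uterus_model(geom: UterusGeometry, materials: dict | None = None,
                       n_membrane: int = 2, n_muscle: int = 6,
                       size_near_mm: float = 1.0, size_far_mm: float = 4.0,
                       n_probe_across: int = 8,
                       out_of_plane_mm: float = 35.0) -> FEModel:
    """Meshed wall + probe system with boundary conditions applied.

    ``out_of_plane_mm`` is the plane-stress section depth; reported forces
    scale linearly with it.  The default is the thickness of the imaged
    slab (30-40 mm section thickness) that the 2D geometry represents.
    """
    materials = materials or default_materials()
    wall = build_wall_mesh(geom, n_membrane=n_membrane, n_muscle=n_muscle,
                           size_near_mm=size_near_mm, size_far_mm=size_far_mm)
    ao, bo = geom.major_axis_mm / 2.0, geom.minor_axis_mm / 2.0
    wallt = geom.wall_thickness_mm
    ai, bi = ao - wallt, bo - wallt
    tip = ellipse_point(geom.contact_theta, ai, bi)
    n_out = ellipse_outward_normal(geom.contact_theta, ai, bi)
    p_nodes, p_elems, tip_chain, control = build_probe_mesh(
        tip, n_out, geom.probe_width_mm, n_across=n_probe_across
    )
    mesh = merge_meshes(wall, p_nodes, p_elems, tip_chain, control)
    _retract_probe_to_clearance(mesh, n_out)

    # symmetry conditions on the major-axis cuts (u_y = 0); with the load
    # at the minor-axis apex the response is symmetric, so the ring is
    # free to ovalize.  The rigid x-translation is removed by pinning u_x
    # on the contact meridian (x = 0), where symmetry demands u_x = 0 —
    # unlike a pin at one cut, this does not obstruct the ovalization.
    fixed = [(int(n), 1) for n in mesh.node_sets["cut_near"]]
    fixed += [(int(n), 1) for n in mesh.node_sets["cut_far"]]
    n_wall_nodes = wall.n_nodes
    if abs(geom.contact_theta - np.pi / 2) < 1e-9:
        meridian = np.where(
            np.abs(mesh.nodes[:n_wall_nodes, 0]) < 1e-12)[0]
        fixed += [(int(n), 0) for n in meridian]
    else:
        # asymmetric contact: restrain the cuts fully instead
        fixed += [(int(n), 0) for n in mesh.node_sets["cut_near"]]
        fixed += [(int(n), 0) for n in mesh.node_sets["cut_far"]]
    bcs = BoundaryConditions(
        fixed=fixed,
        driven_nodes=mesh.node_sets["probe_control"],
        driven_direction=n_out,
    )
    mesh.out_of_plane_thickness = out_of_plane_mm * 1e-3
    return FEModel(mesh=mesh, materials=materials, bcs=bcs)


def _retract_probe_to_clearance(mesh: FEMesh, n_out: np.ndarray) -> None:
    """Shift the probe so it just clears the faceted cavity surface.

    The probe tip is built touching the exact ellipse, but the meshed
    surface is a polyline whose chords cut inside it (by the chord
    sagitta, a few micrometres); without the shift a zero-displacement
    solve would see spurious micro-penetrations.
    """
    from .solver import _contact_forces
    probe_nodes = np.unique(np.concatenate([
        mesh.node_sets["probe_control"], mesh.slave_nodes,
    ]))
    probe_all = np.unique(mesh.elems[mesh.regions == "probe"])
    for _ in range(4):
        f, *_rest, resultant = _contact_forces(mesh, mesh.nodes, 1.0)
        if not np.any(f):
            break
        mesh.nodes[probe_all] -= 2e-5 * n_out  # 20 um per pass
    del probe_nodes


def solve_indentation(model: FEModel, target_displacement_mm: float,
                      n_increments: int = 10) -> FESolution:
    """Ramped, static, frictionless indentation by the tracked deflection."""
    if target_displacement_mm < 0:
        raise ValueError("target displacement must be >= 0")
    return solve(model, target_displacement_mm, n_increments=n_increments)


def reaction_report(solution: FESolution) -> dict:
    """Headline reaction quantities plus the nodal vector field."""
    if not solution.converged:
        raise ValueError("cannot report an unconverged solution")
    return {
        "max_nodal_N": solution.max_nodal_reaction,
        "total_contact_N": solution.total_contact_force,
        "vectors": solution.reactions,
    }


def sensitivity_probe_modulus(geom: UterusGeometry,
                              target_displacement_mm: float,
                              factors=(0.5, 2.0), **model_kw) -> dict:
    """Percent change of the reaction forces when the probe modulus scales.

    Re-solves the model with the cartilage probe modulus multiplied by each
    factor and reports the signed percent change of the maximum nodal
    reaction relative to the unscaled baseline.
    """
    base_mats = default_materials()
    model = build_uterus_model(geom, base_mats, **model_kw)
    base = solve_indentation(model, target_displacement_mm)
    out = {"baseline_max_nodal_N": base.max_nodal_reaction,
           "baseline_total_N": base.total_contact_force,
           "percent_change": {1.0: 0.0}}
    for f in factors:
        mats = dict(base_mats)
        probe = mats["probe"]
        mats["probe"] = Material(probe.elastic_modulus * f,
                                 probe.poisson_ratio)
        m = build_uterus_model(geom, mats, **model_kw)
        sol = solve_indentation(m, target_displacement_mm)
        out["percent_change"][f] = 100.0 * (
            sol.max_nodal_reaction - base.max_nodal_reaction
        ) / base.max_nodal_reaction
    return out
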