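"""Probe-into-clamped-sheet validation scenario.

Mirrors the bench configuration used to validate the 2D modelling
approach: a round-ended rigid-plastic probe pressed a set distance into a
silicone-rubber sheet clamped at both ends, then withdrawn.  Some rig
dimensions (sheet thickness, clamp inner span) are not published, so they
must be supplied by the caller; the loading and unloading branches of the
force-displacement curve coincide because the model is elastic and
frictionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import ConfigurationError
from .mesh import FEMesh, Material, _orient_ccw, _structured_quads, build_probe_mesh
from .solver import BoundaryConditions, FEModel, solve

SILICONE = Material(10.3e6, 0.49)
ABS_PLASTIC = Material(2.6e9, 0.30)


@dataclass(frozen=True)
class SheetScenario:
    span_mm: float | None = None        # clamp inner span
    thickness_mm: float | None = None   # sheet thickness
    probe_diameter_mm: float = 10.0
    indentation_mm: float = 5.0
    sheet_material: Material = SILICONE
    probe_material: Material = ABS_PLASTIC

    def validate(self) -> None:
        missing = [f for f in ("span_mm", "thickness_mm")
                   if getattr(self, f) is None]
        if missing:
            raise ConfigurationError(
                "sheet scenario is missing geometry fields (not published "
                f"for the physical rig): {missing}"
            )
        if self.span_mm <= 0 or self.thickness_mm <= 0:
            raise ConfigurationError("span and thickness must be positive")


def build_sheet_model(scenario: SheetScenario, nx: int = 80,
                      ny: int = 4) -> FEModel:
    scenario.validate()
    W = scenario.span_mm * 1e-3
    t = scenario.thickness_mm * 1e-3
    xs = np.linspace(-W / 2, W / 2, nx + 1)
    ys = np.linspace(-t, 0.0, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)
    elems = _orient_ccw(nodes, _structured_quads(nx, ny))
    idx = np.arange((nx + 1) * (ny + 1)).reshape(nx + 1, ny + 1)

    # probe above the sheet centre, tip touching the top surface (y = 0)
    p_nodes, p_elems, tip_chain, control = build_probe_mesh(
        np.array([0.0, 0.0]), np.array([0.0, -1.0]),
        scenario.probe_diameter_mm,
    )
    offset = len(nodes)
    all_nodes = np.vstack([nodes, p_nodes])
    all_elems = np.vstack([elems, p_elems + offset])
    regions = np.concatenate([
        np.full(len(elems), "sheet", dtype=object),
        np.full(len(p_elems), "probe", dtype=object),
    ]).astype(str)
    mesh = FEMesh(
        nodes=all_nodes, elems=all_elems, regions=regions,
        out_of_plane_thickness=1e-3,
        node_sets={"left": idx[0, :], "right": idx[-1, :],
                   "top_surface": idx[:, -1],
                   "probe_control": control + offset},
        master_chain=idx[:, -1].copy(),
        slave_nodes=tip_chain + offset,
    )
    mesh.check_jacobians()
    fixed = [(int(n), d) for n in idx[0, :] for d in (0, 1)]
    fixed += [(int(n), d) for n in idx[-1, :] for d in (0, 1)]
    bcs = BoundaryConditions(fixed=fixed,
                             driven_nodes=mesh.node_sets["probe_control"],
                             driven_direction=np.array([0.0, -1.0]))
    materials = {"sheet": scenario.sheet_material,
                 "probe": scenario.probe_material}
    model = FEModel(mesh=mesh, materials=materials, bcs=bcs)
    model.penalty_stiffness = 0.01 * scenario.sheet_material.elastic_modulus \
        * mesh.out_of_plane_thickness / 1e-3
    return model


def run_validation_scenario(scenario: SheetScenario, n_increments: int = 10,
                            nx: int = 80, ny: int = 4) -> dict:
    """Loading and unloading force-displacement curves of the sheet test."""
    model = build_sheet_model(scenario, nx=nx, ny=ny)
    target = scenario.indentation_mm
    steps = np.linspace(target / n_increments, target, n_increments)
    sol = solve(model, target, n_increments=n_increments)
    loading = np.array([
        [h["displacement_mm"], h["total_contact_N"]] for h in sol.history
    ])
    # elastic + frictionless: the state depends only on the current probe
    # position, so the unloading branch retraces the loading branch
    unload = []
    for d in steps[::-1]:
        s = solve(model, d, n_increments=max(int(round(d / target
                                                        * n_increments)), 1))
        unload.append([d, s.total_contact_force])
    unloading = np.array(unload)
    return {"loading": loading, "unloading": unloading,
            "peak_force_n": float(loading[-1, 1])}
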