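"""Export of meshes, solutions and reaction histories.

VTK export uses the legacy ASCII format (readable by ParaView and
meshio-based tools); the reaction history is a plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .mesh import FEMesh
from .solver import FESolution


def write_vtk(path, mesh: FEMesh, solution: FESolution | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with optional nodal fields."""
    path = Path(path)
    n = mesh.n_nodes
    lines = [
        "# vtk DataFile Version 3.0",
        "fetalkick FE export",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for p in mesh.nodes:
        lines.append(f"{p[0]:.9e} {p[1]:.9e} 0.0")
    e = mesh.elems
    lines.append(f"CELLS {len(e)} {5 * len(e)}")
    for quad in e:
        lines.append("4 " + " ".join(str(int(i)) for i in quad))
    lines.append(f"CELL_TYPES {len(e)}")
    lines.extend(["9"] * len(e))  # VTK_QUAD
    region_ids = {tag: i for i, tag in enumerate(sorted(set(mesh.regions)))}
    lines.append(f"CELL_DATA {len(e)}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(region_ids[t]) for t in mesh.regions)
    if solution is not None:
        lines.append(f"POINT_DATA {n}")
        lines.append("VECTORS displacement double")
        for u in solution.displacements:
            lines.append(f"{u[0]:.9e} {u[1]:.9e} 0.0")
        lines.append("VECTORS reaction double")
        for r in solution.reactions:
            lines.append(f"{r[0]:.9e} {r[1]:.9e} 0.0")
    path.write_text("\n".join(lines) + "\n")


def write_reaction_history(path, solution: FESolution) -> None:
    df = pd.DataFrame(solution.history)[
        ["increment", "displacement_mm", "total_contact_N", "max_nodal_N"]
    ]
    df.to_csv(path, index=False)


def read_reaction_history(path) -> pd.DataFrame:
    return pd.read_csv(path)
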