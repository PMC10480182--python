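"""Plain-text output: legacy-ASCII VTK structured grids and CSV tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def write_vtk_structured_grid(path, mesh, flow=None, comment="stenoflow field export"):
    """Write the mesh (and optionally the flow fields) as legacy ASCII VTK.

    The grid is exported as a VTK STRUCTURED_GRID of dimensions
    (ni+1, nj+1, 1) with cell data for velocity, pressure, k, eps and
    eddy viscosity when a flow field is given.
    """
    path = Path(path)
    ni, nj = mesh.ni, mesh.nj
    lines = [
        "# vtk DataFile Version 3.0",
        comment,
        "ASCII",
        "DATASET STRUCTURED_GRID",
        f"DIMENSIONS {ni + 1} {nj + 1} 1",
        f"POINTS {(ni + 1) * (nj + 1)} double",
    ]
    # VTK expects x fastest: loop j outer, i inner
    X, Y = mesh.X, mesh.Y
    for j in range(nj + 1):
        for i in range(ni + 1):
            lines.append(f"{X[i, j]:.9e} {Y[i, j]:.9e} 0.0")
    if flow is not None:
        lines.append(f"CELL_DATA {ni * nj}")
        fields = {
            "velocity_magnitude": flow.velocity_magnitude(),
            "u": flow.U,
            "v": flow.V,
            "pressure": flow.p,
            "k": flow.k,
            "epsilon": flow.eps,
            "mu_t": flow.mu_t,
        }
        for name, arr in fields.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            for j in range(nj):
                for i in range(ni):
                    lines.append(f"{arr[i, j]:.9e}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_convergence_csv(path, report):
    """Residual histories as a tidy CSV (iteration, equation, residual)."""
    import pandas as pd

    rows = []
    for name, hist in report.residuals.items():
        for it, r in enumerate(np.asarray(hist), start=1):
            rows.append({"iteration": it, "equation": name, "residual": r})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)
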