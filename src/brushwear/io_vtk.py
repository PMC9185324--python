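"""Optional legacy-ASCII VTK exports for visual inspection.

Writes the minimal legacy (version 2.0) text format: particle snapshots as
POLYDATA point clouds with radius/chain scalars, and the wear map as a
STRUCTURED_POINTS grid over the unfolded surface.  Any VTK-aware viewer
(ParaView etc.) reads these directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .wear import WearMap


def write_particles_vtk(path, positions: np.ndarray, radius: float, chain_of=None) -> None:
    """Particle snapshot as legacy VTK polydata points."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    lines = [
        "# vtk DataFile Version 2.0",
        "brushwear particle snapshot",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.9e} {p[1]:.9e} {p[2]:.9e}" for p in positions]
    lines += [f"POINT_DATA {n}", "SCALARS radius double 1", "LOOKUP_TABLE default"]
    lines += [f"{radius:.9e}"] * n
    if chain_of is not None:
        lines += ["SCALARS chain int 1", "LOOKUP_TABLE default"]
        lines += [str(int(c)) for c in chain_of]
    Path(path).write_text("\n".join(lines) + "\n")


def write_wear_vtk(path, wmap: WearMap) -> None:
    """Wear map as a legacy VTK structured-points grid (u, v, 1)."""
    nu, nv = wmap.grid.shape
    lines = [
        "# vtk DataFile Version 2.0",
        "brushwear unfolded wear map",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nu} {nv} 1",
        "ORIGIN 0 0 0",
        f"SPACING {wmap.cell_size:.9e} {wmap.cell_size:.9e} 1",
        f"POINT_DATA {nu * nv}",
        "SCALARS wear_volume double 1",
        "LOOKUP_TABLE default",
    ]
    lines += [f"{q:.9e}" for q in wmap.grid.T.ravel()]
    Path(path).write_text("\n".join(lines) + "\n")
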