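"""Archard wear accumulation on the unfolded tooth surface.

Closed form (oracle):            Q = K W L / H
Per-contact DEM accumulation:    Q = (K/H) sum_t F_n * delta_t

where F_n is the normal contact force and delta_t = |v_t| dt the sliding
distance in one step.  Wear volume is binned to a 2-D grid over the
*unfolded* measured surface: left plate, down the left groove wall, across
the floor, up the right wall, right plate (axis u), by the y coordinate
(axis v).  The Archard constant K for acrylic-on-enamel is not tabulated;
the default K = 1 reports "wear volume per unit K", and every comparative
output (speed/depth ordering, spatial concentration, symmetry) is
K-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    FACET_FLOOR,
    FACET_LEFT_WALL,
    FACET_RIGHT_WALL,
    MEASURED_FACETS,
    ToothModel,
)


@dataclass(frozen=True)
class WearParams:
    """Archard constants: wear volume Q = K W L / H."""

    archard_constant: float = 1.0  # K, dimensionless
    hardness: float = 0.92e9  # H of the worn surface (enamel), Pa

    def __post_init__(self) -> None:
        if not self.archard_constant > 0:
            raise ValueError("archard_constant must be > 0")
        if not self.hardness > 0:
            raise ValueError("hardness must be > 0")


@dataclass(frozen=True)
class ArchardCase:
    """Closed-form inputs: total normal load W over sliding distance L."""

    load: float  # W, N
    distance: float  # L, m

    def __post_init__(self) -> None:
        if self.load < 0 or self.distance < 0:
            raise ValueError("load and distance must be >= 0")


def archard_total(params: WearParams, case: ArchardCase) -> float:
    """Closed-form Archard wear volume Q = K W L / H in m^3."""
    return params.archard_constant * case.load * case.distance / params.hardness


@dataclass
class SlidingIncrement:
    """One recorded sliding event of a bristle-tooth contact."""

    f_n: float  # normal force, N
    slip: float  # sliding distance |v_t| dt, m
    facet_id: int
    u: float  # unfolded coordinate, m
    v: float  # y + v_offset: y coordinate relative to the grid bottom edge, m
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.f_n < 0 or self.slip < 0:
            raise ValueError("f_n and slip must be >= 0")


@dataclass
class WearMap:
    """2-D grid over the unfolded measured tooth surface.

    ``grid[iu, iv]`` holds the accumulated wear volume Q per cell (m^3);
    ``work[iu, iv]`` the accumulated F_n * delta_t (N m), so that
    grid = (K/H) * work exactly.
    """

    teeth: ToothModel
    params: WearParams = field(default_factory=WearParams)
    cell_size: float = 0.5e-3
    grid: np.ndarray = field(default=None, repr=False)
    work: np.ndarray = field(default=None, repr=False)
    dropped_work: float = 0.0  # increments on excluded facets, N m

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.grid is None:
            self.grid = np.zeros((self.n_u, self.n_v))
        if self.work is None:
            self.work = np.zeros((self.n_u, self.n_v))

    @property
    def n_u(self) -> int:
        return int(np.ceil(self.teeth.unfolded_length / self.cell_size))

    @property
    def n_v(self) -> int:
        # odd so one cell is centred on the y = 0 mid-plane; otherwise wear
        # deposited exactly on the symmetry plane would bin asymmetrically
        nv = int(np.ceil(self.teeth.plate_height / self.cell_size))
        return nv + 1 if nv % 2 == 0 else nv

    @property
    def v_offset(self) -> float:
        """v = y + v_offset maps the symmetry plane y = 0 to the grid
        center."""
        return 0.5 * self.n_v * self.cell_size

    @property
    def total(self) -> float:
        """Total accumulated wear volume, m^3."""
        return float(self.grid.sum())

    def cell_of(self, u: float, v: float) -> tuple[int, int]:
        iu = min(max(int(u / self.cell_size), 0), self.n_u - 1)
        iv = min(max(int(v / self.cell_size), 0), self.n_v - 1)
        return iu, iv

    def groove_band_mask(self, band: float = 2.0e-3) -> np.ndarray:
        """Boolean mask (per u row) of groove facets plus ``band`` of each
        adjacent plate."""
        off = self.teeth.unfold_offsets()
        u_lo = off[FACET_LEFT_WALL] - band
        u_hi = off[FACET_RIGHT_WALL] + self.teeth.groove_depth + band
        u = (np.arange(self.n_u) + 0.5) * self.cell_size
        return (u >= u_lo) & (u <= u_hi)


def accumulate_wear(wmap: WearMap, increments, params: WearParams = None) -> WearMap:
    """Fold a stream of :class:`SlidingIncrement` into the map.

    Each increment adds (K/H) F_n slip to the cell containing its contact
    point; increments on excluded facets (aprons) are dropped and counted in
    ``dropped_work``.
    """
    params = params or wmap.params
    koh = params.archard_constant / params.hardness
    for inc in increments:
        if inc.facet_id not in MEASURED_FACETS:
            wmap.dropped_work += inc.f_n * inc.slip
            continue
        iu, iv = wmap.cell_of(inc.u, inc.v)
        w = inc.f_n * inc.slip
        wmap.work[iu, iv] += w
        wmap.grid[iu, iv] += koh * w
    return wmap


def summarize_wear(wmap: WearMap, band: float = 2.0e-3) -> dict:
    """Summary record of a populated map.

    * ``total``: total wear volume (m^3).
    * ``groove_fraction`` / ``plate_fraction``: share of the total in the
      groove-adjacent band vs the plate interiors.
    * ``groove_density_ratio``: groove-band wear per unit area over plate
      wear per unit area (> 1 means interproximal concentration).
    * ``symmetry_score``: relative L1 difference between the map and its
      top-bottom (v) mirror; 0 for a perfectly symmetric distribution.
    """
    total = wmap.total
    mask = wmap.groove_band_mask(band)
    groove_q = float(wmap.grid[mask, :].sum())
    plate_q = float(wmap.grid[~mask, :].sum())
    area_groove = mask.sum()
    area_plate = (~mask).sum()
    if total > 0:
        groove_density = groove_q / max(area_groove, 1)
        plate_density = plate_q / max(area_plate, 1)
        ratio = groove_density / plate_density if plate_density > 0 else np.inf
        symmetry = float(np.abs(wmap.grid - wmap.grid[:, ::-1]).sum() / total)
        groove_fraction = groove_q / total
        plate_fraction = plate_q / total
    else:
        ratio, symmetry, groove_fraction, plate_fraction = np.nan, 0.0, 0.0, 0.0
    return {
        "total": total,
        "groove_fraction": groove_fraction,
        "plate_fraction": plate_fraction,
        "groove_density_ratio": ratio,
        "symmetry_score": symmetry,
        "dropped_work": wmap.dropped_work,
    }


def wear_map_to_csv(wmap: WearMap, path) -> None:
    """Plain-text export: a header naming cell size and layout, then the
    grid as CSV (rows = unfolded u, columns = v)."""
    header = (
        f"# wear map: cell_size_m={wmap.cell_size}, n_u={wmap.n_u}, n_v={wmap.n_v}, "
        f"unfolded axis u = left plate | left wall | floor | right wall | right plate, "
        f"origin u=0 at the left measured plate edge, v=0 at the plate bottom edge, "
        f"values = wear volume per cell (m^3, per unit K unless K was set)"
    )
    np.savetxt(path, wmap.grid, delimiter=",", header=header, comments="")
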