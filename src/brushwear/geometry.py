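"""Brush assembly, simplified tooth model and scrub-stroke kinematics.

Coordinate convention: x is the stroke direction, y runs across the head
(vertical on the tooth), z is normal to the tooth plane with the occlusal
plate surfaces at z = 0 and overlap positive into the surface.  The brush
head hangs above the plates with the tufts pointing in -z.

The tooth model is two coplanar plates of equal width separated by a
rectangular groove (the interproximal space), plus excluded "apron" plates
continuing the surface on both sides so the brush always rides on a surface
during the stroke; only the two plates and the groove facets are measured.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contact import Facet
from .fiber import BeamSection, FiberChain
from .materials import ACRYLIC, ENAMEL, Material

#: Facet identifiers used by the contact query and the wear map.
FACET_LEFT_APRON = 0
FACET_LEFT_PLATE = 1
FACET_LEFT_WALL = 2
FACET_FLOOR = 3
FACET_RIGHT_WALL = 4
FACET_RIGHT_PLATE = 5
FACET_RIGHT_AUX = 6

MEASURED_FACETS = (
    FACET_LEFT_PLATE,
    FACET_LEFT_WALL,
    FACET_FLOOR,
    FACET_RIGHT_WALL,
    FACET_RIGHT_PLATE,
)


@dataclass
class BrushAssembly:
    """The 42-tuft brush: particle arrays plus chain topology.

    Particle ``i`` of chain ``c`` is stored at flat index ``c * n_particles
    + i``; index 0 is the particle clamped deepest in the head, the last
    index of each chain is the bristle tip.  Positions are in the head
    frame: anchors in the z = 0 head plane, tips at z = -(n-1) l0.
    """

    n_rows: int
    n_cols: int
    head_length: float
    head_width: float
    beam_length: float
    particle_diameter: float
    chain: FiberChain
    material: Material
    positions: np.ndarray  # (N, 3) head-frame
    clamped: np.ndarray  # (N,) bool
    chain_of: np.ndarray  # (N,) chain index
    anchors: np.ndarray  # (n_chains, 2) tuft x-y on the head

    @property
    def n_chains(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def particle_radius(self) -> float:
        return self.particle_diameter / 2.0

    @property
    def particle_mass(self) -> float:
        """Solid-cylinder-segment mass rho A l0 of the aggregate beam."""
        section = BeamSection(self.particle_diameter)
        return self.material.density * section.area * self.chain.l0

    @property
    def tip_indices(self) -> np.ndarray:
        n = self.chain.n_particles
        return np.arange(self.n_chains) * n + (n - 1)

    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) particle index pairs of all chain bonds."""
        n = self.chain.n_particles
        out = []
        for c in range(self.n_chains):
            base = c * n
            for i in range(n - 1):
                out.append((base + i, base + i + 1))
        return np.array(out, dtype=np.int64)

    def joints(self) -> np.ndarray:
        """(n_joints, 3) particle index triples of all bending joints."""
        n = self.chain.n_particles
        out = []
        for c in range(self.n_chains):
            base = c * n
            for i in range(1, n - 1):
                out.append((base + i - 1, base + i, base + i + 1))
        return np.array(out, dtype=np.int64)


def build_brush(
    n_rows: int = 3,
    n_cols: int = 14,
    head_length: float = 27.5e-3,
    head_width: float = 10.2e-3,
    beam_length: float = 10.8e-3,
    particle_diameter: float = 1.8e-3,
    n_particles: int = 8,
    n_clamped: int = 2,
    material: Material = ACRYLIC,
) -> BrushAssembly:
    """Build the tuft grid: ``n_rows x n_cols`` chains of ``n_particles``
    particles each, anchored on the head and hanging in -z.

    The tuft grid is rectangular with uniform spacing (head area and tuft
    count are prescribed, the layout is not); spacing below one particle
    diameter is rejected because chains would interpenetrate at rest.
    """
    dx = head_length / n_cols
    dy = head_width / n_rows
    if min(dx, dy) < particle_diameter:
        raise ValueError(
            f"tuft spacing ({dx * 1e3:.2f} x {dy * 1e3:.2f} mm) below the tuft "
            f"diameter {particle_diameter * 1e3:.2f} mm: initial interpenetration"
        )
    section = BeamSection(particle_diameter)
    chain = FiberChain.from_beam(material, section, beam_length, n_particles, n_clamped)

    xs = (np.arange(n_cols) - (n_cols - 1) / 2.0) * dx
    ys = (np.arange(n_rows) - (n_rows - 1) / 2.0) * dy
    n_chains = n_rows * n_cols
    positions = np.zeros((n_chains * n_particles, 3))
    clamped = np.zeros(n_chains * n_particles, dtype=bool)
    chain_of = np.zeros(n_chains * n_particles, dtype=np.int64)
    anchors = np.zeros((n_chains, 2))
    c = 0
    for iy in range(n_rows):
        for ix in range(n_cols):
            base = c * n_particles
            anchors[c] = (xs[ix], ys[iy])
            for i in range(n_particles):
                positions[base + i] = (xs[ix], ys[iy], -i * chain.l0)
                clamped[base + i] = i < n_clamped
            chain_of[base : base + n_particles] = c
            c += 1
    return BrushAssembly(
        n_rows=n_rows,
        n_cols=n_cols,
        head_length=head_length,
        head_width=head_width,
        beam_length=beam_length,
        particle_diameter=particle_diameter,
        chain=chain,
        material=material,
        positions=positions,
        clamped=clamped,
        chain_of=chain_of,
        anchors=anchors,
    )


@dataclass
class ToothModel:
    """Two coplanar plates + rectangular interproximal groove, with apron
    plates on both sides excluded from all measurement."""

    groove_center: float = 0.0  # x of the groove midline, m
    groove_width: float = 2.4e-3
    groove_depth: float = 3.0e-3
    measured_span: float = 28.0e-3  # total plate+groove extent in x
    plate_height: float = 16.0e-3  # extent in y
    apron_length: float = 36.0e-3  # excluded surface continuing each side
    material: Material = field(default_factory=lambda: ENAMEL)

    def __post_init__(self) -> None:
        if self.plate_width <= self.groove_width:
            raise ValueError(
                f"groove ({self.groove_width * 1e3:.1f} mm) wider than each plate "
                f"({self.plate_width * 1e3:.1f} mm)"
            )
        if not self.groove_depth > 0:
            raise ValueError("groove_depth must be > 0")

    @property
    def plate_width(self) -> float:
        """Width of each measured plate (equal left and right)."""
        return (self.measured_span - self.groove_width) / 2.0

    @property
    def groove_left(self) -> float:
        return self.groove_center - self.groove_width / 2.0

    @property
    def groove_right(self) -> float:
        return self.groove_center + self.groove_width / 2.0

    @property
    def measured_x(self) -> tuple[float, float]:
        h = self.measured_span / 2.0
        return (self.groove_center - h, self.groove_center + h)

    @property
    def surface_x(self) -> tuple[float, float]:
        x0, x1 = self.measured_x
        return (x0 - self.apron_length, x1 + self.apron_length)

    @property
    def unfolded_length(self) -> float:
        """Length of the unfolded measured surface: plate + wall + floor +
        wall + plate."""
        return self.measured_span - self.groove_width + 2.0 * self.groove_depth + self.groove_width

    def unfold_offsets(self) -> np.ndarray:
        """Start coordinate of each measured facet on the unfolded axis
        (indexed by facet id 1..5)."""
        w = self.plate_width
        d = self.groove_depth
        g = self.groove_width
        return np.array([np.nan, 0.0, w, w + d, w + d + g, w + 2 * d + g])

    def facets(self) -> dict[int, Facet]:
        """Bounded facets of the model (for the generic detector and VTK
        export); the engine uses the equivalent closed-form profile query."""
        x0, x1 = self.measured_x
        s0, s1 = self.surface_x
        y0 = -self.plate_height / 2.0
        h = self.plate_height
        d = self.groove_depth
        ey = np.array([0.0, 1.0, 0.0])

        def rect(ox, oz, eu, name):
            return Facet(np.array([ox, y0, oz]), np.asarray(eu, float), ey * h, name)

        return {
            FACET_LEFT_APRON: rect(s0, 0.0, [x0 - s0, 0, 0], "left_apron"),
            FACET_LEFT_PLATE: rect(x0, 0.0, [self.plate_width, 0, 0], "left_plate"),
            # left wall: outward normal +x (into the groove)
            FACET_LEFT_WALL: Facet(
                np.array([self.groove_left, y0, -d]),
                ey * h,
                np.array([0.0, 0.0, d]),
                "left_wall",
            ),
            FACET_FLOOR: rect(self.groove_left, -d, [self.groove_width, 0, 0], "floor"),
            # right wall: outward normal -x
            FACET_RIGHT_WALL: Facet(
                np.array([self.groove_right, y0, 0.0]),
                ey * h,
                np.array([0.0, 0.0, -d]),
                "right_wall",
            ),
            FACET_RIGHT_PLATE: rect(self.groove_right, 0.0, [self.plate_width, 0, 0], "right_plate"),
            FACET_RIGHT_AUX: rect(x1, 0.0, [s1 - x1, 0, 0], "right_aux"),
        }

    def facet_of_point(self, px: float, pz: float) -> int:
        """Facet id owning a surface point (top-surface points go to the
        plate/apron containing them, wall/floor points to the groove
        facets)."""
        if pz >= -1e-12:  # on the top surface
            x0, x1 = self.measured_x
            if px <= self.groove_left:
                return FACET_LEFT_PLATE if px >= x0 else FACET_LEFT_APRON
            if px >= self.groove_right:
                return FACET_RIGHT_PLATE if px <= x1 else FACET_RIGHT_AUX
        if pz <= -self.groove_depth + 1e-12:
            return FACET_FLOOR
        return FACET_LEFT_WALL if px <= self.groove_center else FACET_RIGHT_WALL

    def unfolded_coord(self, facet_id: int, px: float, pz: float) -> float:
        """Map a surface point to the unfolded coordinate u in
        [0, unfolded_length] (measured facets only)."""
        off = self.unfold_offsets()
        x0, x1 = self.measured_x
        if facet_id == FACET_LEFT_PLATE:
            return off[1] + (px - x0)
        if facet_id == FACET_LEFT_WALL:
            return off[2] + (-pz)
        if facet_id == FACET_FLOOR:
            return off[3] + (px - self.groove_left)
        if facet_id == FACET_RIGHT_WALL:
            return off[4] + (pz + self.groove_depth)
        if facet_id == FACET_RIGHT_PLATE:
            return off[5] + (px - self.groove_right)
        raise ValueError(f"facet {facet_id} is not measured")


def build_teeth(**kwargs) -> ToothModel:
    """Construct the tooth model (see :class:`ToothModel` for parameters)."""
    return ToothModel(**kwargs)


def tooth_profile_contacts(
    center: np.ndarray, radius: float, teeth: ToothModel
) -> list[tuple[float, np.ndarray, np.ndarray, int]]:
    """Reference closed-form sphere-vs-tooth contact query.

    The tooth cross-section (in x-z) is the half-plane z <= 0 minus the
    rectangular groove notch; its boundary is 5 segments (plate, wall,
    floor, wall, plate).  Returns a list of ``(delta_n, normal, point,
    facet_id)``.  Face (interior-projection) contacts are preferred over
    edge/corner contacts, and duplicate closest points are merged, so a
    sphere never collects two contacts for one surface patch.  The engine
    kernel implements the identical rule.
    """
    cx, cy, cz = float(center[0]), float(center[1]), float(center[2])
    gl, gr = teeth.groove_left, teeth.groove_right
    d = teeth.groove_depth
    s0, s1 = teeth.surface_x
    # segments as (ax, az, bx, bz, nx, nz): endpoints + outward face normal
    segments = (
        (s0, 0.0, gl, 0.0, 0.0, 1.0),
        (gl, -d, gl, 0.0, 1.0, 0.0),
        (gl, -d, gr, -d, 0.0, 1.0),
        (gr, -d, gr, 0.0, -1.0, 0.0),
        (gr, 0.0, s1, 0.0, 0.0, 1.0),
    )
    face_hits, edge_hits = [], []
    for ax, az, bx, bz, nx, nz in segments:
        ex, ez = bx - ax, bz - az
        seg_len2 = ex * ex + ez * ez
        t = ((cx - ax) * ex + (cz - az) * ez) / seg_len2
        tc = min(max(t, 0.0), 1.0)
        px, pz = ax + tc * ex, az + tc * ez
        interior = 1e-9 < tc < 1.0 - 1e-9
        if interior:
            # signed face distance: negative if the center sits behind the
            # face (inside the tooth solid)
            s = (cx - px) * nx + (cz - pz) * nz
            if s < radius:
                face_hits.append(
                    (radius - s, np.array([nx, 0.0, nz]), np.array([px, cy, pz]), s)
                )
        else:
            dx, dz = cx - px, cz - pz
            dist = math.hypot(dx, dz)
            if 0.0 < dist < radius:
                edge_hits.append(
                    (
                        radius - dist,
                        np.array([dx / dist, 0.0, dz / dist]),
                        np.array([px, cy, pz]),
                        dist,
                    )
                )
    if face_hits and min(h[3] for h in face_hits) < 0.0:
        # center inside the solid: push out through the nearest face only
        hits = [max(face_hits, key=lambda h: h[3])]
    elif face_hits:
        hits = face_hits
    else:
        hits = []
        for hit in edge_hits:  # merge duplicate corner hits
            if not any(np.allclose(hit[2], kept[2], atol=1e-12) for kept in hits):
                hits.append(hit)
    out = []
    for delta, normal, point, _meta in hits:
        out.append((delta, normal, point, teeth.facet_of_point(point[0], point[2])))
    return out


@dataclass(frozen=True)
class MotionProfile:
    """Prescribed scrub-stroke kinematics of the brush head.

    One cycle is a forward stroke of L/2 followed by a backward stroke of
    L/2 at constant speed V with instantaneous reversal; total sliding
    distance L (default 56 mm, twice the 28 mm tooth-model span).  The
    brushing depth d_z sets the head height so the undeformed tip spheres
    overlap the plate surface by d_z.
    """

    speed: float = 0.10  # V, m/s
    depth: float = 0.9e-3  # d_z, m
    stroke: float = 56.0e-3  # L, total two-stroke distance, m

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError("speed must be > 0")
        if not self.depth > 0:
            raise ValueError("depth must be > 0")
        if not self.stroke > 0:
            raise ValueError("stroke must be > 0")

    @property
    def duration(self) -> float:
        """Total run time L / V."""
        return self.stroke / self.speed

    @property
    def turnaround(self) -> float:
        return 0.5 * self.duration

    def crossing_times(self) -> tuple[float, float]:
        """Times at which the head center crosses the groove midline
        (stroke fractions 1/5 forward and 4/5 backward)."""
        return (0.2 * self.stroke / self.speed, 0.8 * self.stroke / self.speed)

    def start_center(self, groove_center: float = 0.0) -> float:
        """Head-center start x: the center reaches the groove midline after
        travelling L/5."""
        return groove_center - 0.2 * self.stroke

    def head_height(self, tip_radius: float, beam_length: float) -> float:
        """z of the head anchor plane so the undeformed tip overlap is d_z."""
        return (tip_radius - self.depth) + beam_length


def head_position(t: float, motion: MotionProfile) -> tuple[float, float]:
    """Head displacement s(t) along +x and velocity at time t.

    Constant-speed translation, instantaneous reversal at t = L/(2V);
    t outside [0, L/V] is rejected.
    """
    if not 0.0 <= t <= motion.duration * (1.0 + 1e-12):
        raise ValueError(f"t={t} outside the run window [0, {motion.duration}]")
    half = motion.turnaround
    if t <= half:
        return motion.speed * t, motion.speed
    return motion.speed * half - motion.speed * (t - half), -motion.speed
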