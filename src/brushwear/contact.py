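"""Hertz-Mindlin pairwise contact mechanics.

Sphere-sphere (bristle-bristle) and sphere-facet (bristle-tooth) contact
detection and force evaluation.  The normal force is the Hertz spring

    F_n = (4/3) E* sqrt(R*) delta_n^{3/2}  -  c_n v_n,     c_n = 2 sqrt(5/6) |beta| sqrt(S_n m*)

with S_n = 2 E* sqrt(R* delta_n) and beta = ln e / sqrt(ln^2 e + pi^2);
the tangential force is the Mindlin spring

    F_t = -8 G* sqrt(R* delta_n) delta_t  -  c_t v_t,      c_t = 2 sqrt(5/6) |beta| sqrt(S_t m*)

capped by the Coulomb limit mu |F_n| with the spring elongation delta_t
rescaled onto the cap.  beta is negative for e < 1; the damping terms are
written with |beta| and an explicit minus so they always oppose the relative
approach / slip velocity.  The total normal force is clamped at >= 0 (no
cohesion is modelled).

These functions are the reference implementation; the brushing engine
(:mod:`brushwear.engine`) inlines the same formulas in its compiled kernel
and is cross-checked against this module in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .materials import Material

_DAMP = 2.0 * math.sqrt(5.0 / 6.0)


def restitution_beta(e: float) -> float:
    """Damping ratio beta = ln e / sqrt(ln^2 e + pi^2); 0 at e = 1, negative
    for e < 1."""
    if not 0 < e <= 1:
        raise ValueError(f"restitution must be in (0, 1], got {e}")
    if e == 1.0:
        return 0.0
    ln_e = math.log(e)
    return ln_e / math.sqrt(ln_e * ln_e + math.pi * math.pi)


@dataclass(frozen=True)
class ContactPair:
    """Equivalent single-body properties of a contacting pair.

    ``eq_radius``/``eq_mass`` are the partner-combined R* and m*; a plane
    partner contributes 1/R = 0 and 1/m = 0.  ``damping_ratio`` stores the
    signed beta of the pair's restitution coefficient.
    """

    eq_elastic_modulus: float  # E*, Pa
    eq_shear_modulus: float  # G*, Pa
    eq_radius: float  # R*, m
    eq_mass: float  # m*, kg
    damping_ratio: float  # beta, <= 0
    friction: float  # mu

    def __post_init__(self) -> None:
        for attr in ("eq_elastic_modulus", "eq_shear_modulus", "eq_radius", "eq_mass"):
            if not getattr(self, attr) > 0:
                raise ValueError(f"{attr} must be > 0, got {getattr(self, attr)}")
        if self.damping_ratio > 0:
            raise ValueError("damping_ratio (beta) must be <= 0")
        if self.friction < 0:
            raise ValueError("friction must be >= 0")


@dataclass
class Contact:
    """An active contact: geometry plus (mutable) tangential history."""

    point: np.ndarray  # contact point, m
    normal: np.ndarray  # unit normal, from partner b towards a
    delta_n: float  # normal overlap, m
    partner_a: int = -1
    partner_b: int = -1
    delta_t: Optional[np.ndarray] = None  # accumulated tangential slip, m

    def __post_init__(self) -> None:
        if self.delta_n < 0:
            raise ValueError("delta_n must be >= 0 for an active contact")
        if self.delta_t is None:
            self.delta_t = np.zeros(3)


def effective_pair_properties(
    mat_a: Material,
    mat_b: Material,
    radius_a: float,
    radius_b: Optional[float] = None,
    mass_a: float = 1.0,
    mass_b: Optional[float] = None,
    restitution: Optional[float] = None,
) -> ContactPair:
    """Combine two bodies' materials into equivalent contact properties.

    ``radius_b=None`` / ``mass_b=None`` denote a plane (infinite radius and
    mass), so R* = radius_a and m* = mass_a.  The pair restitution defaults
    to min(e_a, e_b) unless given explicitly.
    """
    if not radius_a > 0:
        raise ValueError(f"radius_a must be > 0, got {radius_a}")
    if radius_b is not None and not radius_b > 0:
        raise ValueError(f"radius_b must be > 0, got {radius_b}")
    if not mass_a > 0:
        raise ValueError(f"mass_a must be > 0, got {mass_a}")

    inv_e = (1.0 - mat_a.poisson_ratio**2) / mat_a.elastic_modulus + (
        1.0 - mat_b.poisson_ratio**2
    ) / mat_b.elastic_modulus
    inv_g = (2.0 - mat_a.poisson_ratio) / mat_a.shear_modulus + (
        2.0 - mat_b.poisson_ratio
    ) / mat_b.shear_modulus
    inv_r = 1.0 / radius_a + (0.0 if radius_b is None else 1.0 / radius_b)
    inv_m = 1.0 / mass_a + (0.0 if mass_b is None else 1.0 / mass_b)

    e = restitution if restitution is not None else min(mat_a.restitution, mat_b.restitution)
    return ContactPair(
        eq_elastic_modulus=1.0 / inv_e,
        eq_shear_modulus=1.0 / inv_g,
        eq_radius=1.0 / inv_r,
        eq_mass=1.0 / inv_m,
        damping_ratio=restitution_beta(e),
        friction=mat_a.friction_with(mat_b),
    )


def normal_force(pair: ContactPair, delta_n: float, v_n_rel: float = 0.0) -> float:
    """Signed normal force along the contact normal (positive = repulsive).

    ``v_n_rel`` is the normal component of the relative velocity of body a
    with respect to body b along the normal (positive = separating).  The
    total is clamped at zero: the contact cannot pull.
    """
    if delta_n < 0:
        raise ValueError(f"delta_n must be >= 0, got {delta_n}")
    if delta_n == 0.0:
        return 0.0
    f_el = (4.0 / 3.0) * pair.eq_elastic_modulus * math.sqrt(pair.eq_radius) * delta_n**1.5
    s_n = 2.0 * pair.eq_elastic_modulus * math.sqrt(pair.eq_radius * delta_n)
    c_n = _DAMP * abs(pair.damping_ratio) * math.sqrt(s_n * pair.eq_mass)
    return max(0.0, f_el - c_n * v_n_rel)


def tangential_force(
    pair: ContactPair,
    delta_n: float,
    delta_t: np.ndarray,
    v_t_rel: np.ndarray,
    f_n: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mindlin tangential force with Coulomb cap.

    Returns ``(F_t, delta_t)`` where ``delta_t`` is the (possibly rescaled)
    tangential spring elongation to carry to the next step.  ``f_n`` is the
    current normal force magnitude for the Coulomb limit; if omitted it is
    evaluated from ``delta_n`` at zero normal velocity.
    """
    if not delta_n > 0:
        raise ValueError("tangential_force requires an active contact (delta_n > 0)")
    delta_t = np.asarray(delta_t, dtype=float)
    v_t_rel = np.asarray(v_t_rel, dtype=float)
    s_t = 8.0 * pair.eq_shear_modulus * math.sqrt(pair.eq_radius * delta_n)
    c_t = _DAMP * abs(pair.damping_ratio) * math.sqrt(s_t * pair.eq_mass)
    f_t = -s_t * delta_t - c_t * v_t_rel
    if f_n is None:
        f_n = normal_force(pair, delta_n)
    cap = pair.friction * abs(f_n)
    mag = float(np.linalg.norm(f_t))
    if mag > cap:
        if mag > 0:
            f_t = f_t * (cap / mag)
        # truncate the spring so it stores exactly the capped force
        delta_t = -f_t / s_t
    return f_t, delta_t


@dataclass(frozen=True)
class Facet:
    """A bounded rectangular planar facet.

    Spanned by two orthogonal edge vectors from ``origin``; the outward
    normal is ``unit(edge_u x edge_v)``.
    """

    origin: np.ndarray
    edge_u: np.ndarray
    edge_v: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        n = np.cross(self.edge_u, self.edge_v)
        if np.linalg.norm(n) <= 0:
            raise ValueError(f"degenerate facet {self.name!r}: zero area")

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.edge_u, self.edge_v)
        return n / np.linalg.norm(n)

    def closest_point(self, point: np.ndarray) -> np.ndarray:
        """Closest point on the bounded facet (clamped projection)."""
        d = np.asarray(point, dtype=float) - self.origin
        lu = np.linalg.norm(self.edge_u)
        lv = np.linalg.norm(self.edge_v)
        u_hat = self.edge_u / lu
        v_hat = self.edge_v / lv
        pu = min(max(float(d @ u_hat), 0.0), lu)
        pv = min(max(float(d @ v_hat), 0.0), lv)
        return self.origin + pu * u_hat + pv * v_hat


def detect_sphere_plane(center: np.ndarray, radius: float, facet: Facet) -> Optional[Contact]:
    """Sphere vs bounded facet: contact iff the closest point on the facet is
    within ``radius`` of the center.  Edge/corner cases use the clamped
    closest point, so the returned normal is the facet normal for interior
    hits and the edge/corner direction otherwise."""
    if not radius > 0:
        raise ValueError(f"radius must be > 0, got {radius}")
    center = np.asarray(center, dtype=float)
    p = facet.closest_point(center)
    d = center - p
    dist = float(np.linalg.norm(d))
    if dist >= radius:
        return None
    if dist <= 0:
        raise ValueError("sphere center lies exactly on the facet: normal undefined")
    return Contact(point=p, normal=d / dist, delta_n=radius - dist)


def detect_sphere_sphere(
    center_a: np.ndarray,
    radius_a: float,
    center_b: np.ndarray,
    radius_b: float,
    bonded: bool = False,
) -> Optional[Contact]:
    """Sphere vs sphere: contact iff center separation < r_a + r_b.

    ``bonded=True`` marks a pair adjacent in the same fiber chain, whose
    interaction is the chain bond, not a contact: always returns None.
    """
    if bonded:
        return None
    center_a = np.asarray(center_a, dtype=float)
    center_b = np.asarray(center_b, dtype=float)
    d = center_a - center_b
    dist = float(np.linalg.norm(d))
    if dist == 0.0:
        raise ValueError("coincident sphere centers: contact normal undefined")
    if dist >= radius_a + radius_b:
        return None
    n = d / dist
    point = center_b + n * (radius_b - 0.5 * (radius_a + radius_b - dist))
    return Contact(point=point, normal=n, delta_n=radius_a + radius_b - dist)
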