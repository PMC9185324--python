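"""Worm-like-chain (WLC) connected-particle fiber model.

One bristle tuft is a chain of N = 8 particles joined by beam bonds that
carry three elastic energies:

    stretching   H_S = 1/2 k_s  sum_i (l_i - l_0)^2
    bending      H_B = k_bend   sum_joints (1 - t_hat_i . t_hat_{i+1})
    torsion      H_T = 1/2 k_T  sum_joints (gamma_i - gamma_0)^2

where l_i is the bond length, t_hat_i the unit bond vector and gamma_i the
scalar twist tracked per joint.  Forces are the exact analytic gradients of
these energies (verified against finite differences in the tests).

Stiffnesses follow the standard lattice-beam discretisation of a continuum
beam of Young's modulus E, shear modulus G and circular section:

    k_s = E A / l_0,   k_bend = E I / l_0,   k_T = G J / l_0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import Material


@dataclass(frozen=True)
class BeamSection:
    """Circular beam cross-section derived from the tuft diameter."""

    diameter: float  # m

    def __post_init__(self) -> None:
        if not self.diameter > 0:
            raise ValueError(f"diameter must be > 0, got {self.diameter}")

    @property
    def area(self) -> float:
        """Cross-section area A = pi d^2 / 4."""
        return math.pi * self.diameter**2 / 4.0

    @property
    def area_moment(self) -> float:
        """Area moment of inertia I = pi d^4 / 64."""
        return math.pi * self.diameter**4 / 64.0

    @property
    def polar_moment(self) -> float:
        """Polar moment J = pi d^4 / 32."""
        return math.pi * self.diameter**4 / 32.0


def calibrate_stiffness(
    material: Material, section: BeamSection, l0: float
) -> tuple[float, float, float]:
    """Map continuum beam properties to the chain stiffness triple
    ``(k_s, k_bend, k_T)``; all three scale as 1/l0."""
    if not l0 > 0:
        raise ValueError(f"l0 must be > 0, got {l0}")
    e = material.elastic_modulus
    g = material.shear_modulus
    return (
        e * section.area / l0,
        e * section.area_moment / l0,
        g * section.polar_moment / l0,
    )


@dataclass
class FiberChain:
    """One tuft: an ordered chain of particles with WLC stiffnesses.

    The first ``n_clamped`` particles are kinematically slaved to the brush
    head (their equations of motion are never integrated), mirroring the way
    tufts are anchored in a real brush head.
    """

    n_particles: int
    l0: float
    k_s: float
    k_bend: float
    k_t: float
    gamma0: float = 0.0
    n_clamped: int = 2
    twist: np.ndarray = field(default=None, repr=False)  # per-joint, rad

    def __post_init__(self) -> None:
        if self.n_particles < 3:
            raise ValueError("a fiber chain needs at least 3 particles")
        if not self.l0 > 0:
            raise ValueError(f"l0 must be > 0, got {self.l0}")
        for name in ("k_s", "k_bend", "k_t"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.n_clamped < self.n_particles:
            raise ValueError("n_clamped must leave at least one free particle")
        if self.twist is None:
            self.twist = np.full(self.n_bonds, self.gamma0, dtype=float)

    @property
    def n_bonds(self) -> int:
        return self.n_particles - 1

    @property
    def n_joints(self) -> int:
        """Interior particles where two bonds meet."""
        return self.n_particles - 2

    # twist gamma_i is tracked per bond (relative rotation of consecutive
    # particles about the bond axis), so the torsion sum has n_bonds terms

    @classmethod
    def from_beam(
        cls,
        material: Material,
        section: BeamSection,
        length: float,
        n_particles: int = 8,
        n_clamped: int = 2,
    ) -> "FiberChain":
        l0 = length / (n_particles - 1)
        k_s, k_bend, k_t = calibrate_stiffness(material, section, l0)
        return cls(n_particles, l0, k_s, k_bend, k_t, n_clamped=n_clamped)


def _bond_vectors(chain: FiberChain, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (chain.n_particles, 3):
        raise ValueError(f"positions must have shape ({chain.n_particles}, 3)")
    if not np.all(np.isfinite(positions)):
        raise ValueError("positions must be finite")
    bonds = positions[1:] - positions[:-1]
    lengths = np.linalg.norm(bonds, axis=1)
    if np.any(lengths == 0.0):
        raise ValueError("coincident adjacent particles: bond direction undefined")
    return bonds, lengths


def stretching_energy(chain: FiberChain, positions: np.ndarray) -> float:
    _, lengths = _bond_vectors(chain, positions)
    return 0.5 * chain.k_s * float(np.sum((lengths - chain.l0) ** 2))


def stretching_forces(chain: FiberChain, positions: np.ndarray) -> np.ndarray:
    """Per-particle forces -dH_S/dx: each bond pulls its two particles
    together (or pushes apart) along the bond axis with magnitude
    k_s (l_i - l_0)."""
    bonds, lengths = _bond_vectors(chain, positions)
    t_hat = bonds / lengths[:, None]
    f_bond = chain.k_s * (lengths - chain.l0)[:, None] * t_hat  # on lower particle, +axis
    forces = np.zeros((chain.n_particles, 3))
    forces[:-1] += f_bond
    forces[1:] -= f_bond
    return forces


def bending_energy(chain: FiberChain, positions: np.ndarray) -> float:
    bonds, lengths = _bond_vectors(chain, positions)
    t_hat = bonds / lengths[:, None]
    cos = np.sum(t_hat[:-1] * t_hat[1:], axis=1)
    return chain.k_bend * float(np.sum(1.0 - cos))


def bending_forces(chain: FiberChain, positions: np.ndarray) -> np.ndarray:
    """Per-particle forces -dH_B/dx for H_B = k_bend sum (1 - t1.t2),
    with the analytic gradient through the bond-vector normalisation."""
    bonds, lengths = _bond_vectors(chain, positions)
    t_hat = bonds / lengths[:, None]
    forces = np.zeros((chain.n_particles, 3))
    for j in range(chain.n_joints):
        t1, t2 = t_hat[j], t_hat[j + 1]
        l1, l2 = lengths[j], lengths[j + 1]
        c = float(t1 @ t2)
        # d(t1.t2)/dx on the three particles of the joint
        g_prev = -(t2 - c * t1) / l1
        g_next = (t1 - c * t2) / l2
        g_mid = -(g_prev + g_next)
        # F = -dH/dx = +k_bend * d(t1.t2)/dx
        forces[j] += chain.k_bend * g_prev
        forces[j + 1] += chain.k_bend * g_mid
        forces[j + 2] += chain.k_bend * g_next
    return forces


def torsion_energy(chain: FiberChain, twist: np.ndarray = None) -> float:
    gamma = np.asarray(chain.twist if twist is None else twist, dtype=float)
    if gamma.shape != (chain.n_bonds,):
        raise ValueError(f"twist must have shape ({chain.n_bonds},)")
    return 0.5 * chain.k_t * float(np.sum((gamma - chain.gamma0) ** 2))


def torsion_torques(chain: FiberChain, twist: np.ndarray = None) -> np.ndarray:
    """Restoring torque -dH_T/dgamma = -k_T (gamma_i - gamma_0) per joint,
    acting about the local bond axis."""
    gamma = np.asarray(chain.twist if twist is None else twist, dtype=float)
    if gamma.shape != (chain.n_bonds,):
        raise ValueError(f"twist must have shape ({chain.n_bonds},)")
    return -chain.k_t * (gamma - chain.gamma0)


def wlc_forces(chain: FiberChain, positions: np.ndarray) -> np.ndarray:
    """Total internal WLC force (stretching + bending) per particle."""
    return stretching_forces(chain, positions) + bending_forces(chain, positions)


def wlc_energy(chain: FiberChain, positions: np.ndarray, twist: np.ndarray = None) -> float:
    """Total WLC elastic energy H_S + H_B + H_T."""
    return (
        stretching_energy(chain, positions)
        + bending_energy(chain, positions)
        + torsion_energy(chain, twist)
    )
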