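"""Shared helpers for binary-collision scenarios built on the raw engine."""

import math

import numpy as np

from brushwear.contact import effective_pair_properties
from brushwear.engine import Engine, EngineParams
from brushwear.materials import ACRYLIC

R = 0.9e-3
M = 4.6e-6


def free_particles(positions, velocities, teeth=None, e=1.0, mu=0.0, gamma=0.0, dt=None):
    """Engine holding unbonded spheres (no chains)."""
    n = len(positions)
    eng = Engine(
        positions=np.asarray(positions, float),
        masses=np.full(n, M),
        radius=R,
        clamped=np.zeros(n, bool),
        bonds=np.zeros((0, 2), int),
        bond_ks=np.zeros(0),
        bond_l0=np.zeros(0),
        joints=np.zeros((0, 3), int),
        joint_kb=np.zeros(0),
        material=ACRYLIC.with_restitution(e),
        teeth=teeth,
        params=EngineParams(restitution=e, friction=mu, gamma_bg=gamma, pair_contacts=True),
        dt=dt,
    )
    eng.vel[:] = velocities
    return eng


def binary_collision_dt(v0):
    """dt = dt_crit/50 at the maximum Hertz overlap of a head-on collision."""
    pp = effective_pair_properties(ACRYLIC, ACRYLIC, R, R, M, M)
    mstar = pp.eq_mass
    dmax = (15.0 / 16.0 * mstar * v0**2 / (pp.eq_elastic_modulus * math.sqrt(pp.eq_radius))) ** 0.4
    k = 2.0 * pp.eq_elastic_modulus * math.sqrt(pp.eq_radius * dmax)
    return 2.0 * math.sqrt(mstar / k) / 50.0


def run_binary(e, v0=0.5):
    """Head-on equal-sphere collision, returned after full separation."""
    dt = binary_collision_dt(v0)
    gap = 0.2 * R
    eng = free_particles(
        [[0, 0, 0], [2 * R + gap, 0, 0]],
        [[v0, 0, 0], [-v0, 0, 0]],
        e=e,
        dt=dt,
    )
    eng.step(int((4 * gap / v0) / dt))
    assert eng.pos[1, 0] - eng.pos[0, 0] > 2 * R
    return eng
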