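"""Static cantilever validation of the WLC tuft beam.

A single 8-particle tuft (top two particles clamped) is loaded with a dead
transverse tip force, relaxed to static equilibrium with the DEM engine,
and compared against the inextensible large-deflection cantilever
(elastica) solved as a boundary-value problem.

Reference length convention
---------------------------
A chain of particles spaced l0 with joint springs k_bend = EI/l0 is the
standard staggered discretisation of a continuum beam in which particle k
sits at arclength (k - 1/2) l0 and the clamp plane lies half a segment
above the first free joint.  The equivalent continuum length of the
8-particle, 2-clamped tuft is therefore

    L_eff = (n_free_joints + 1/2) l0 = 6.5 l0

(6 active joints); with this convention the small-load discrete tip
compliance matches Euler-Bernoulli F L^3/(3EI) to ~0.6%.  The same L_eff
is used on both sides of the comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .engine import Engine, EngineParams
from .fiber import BeamSection, FiberChain
from .materials import ACRYLIC, Material


@dataclass
class CantileverCase:
    """Tip-loaded cantilever matching the brushing tuft discretisation."""

    load: float  # tip force F, N
    material: Material = field(default_factory=lambda: ACRYLIC)
    section: BeamSection = field(default_factory=lambda: BeamSection(1.8e-3))
    beam_length: float = 10.8e-3
    n_particles: int = 8
    n_clamped: int = 2

    def __post_init__(self) -> None:
        if self.load < 0:
            raise ValueError("load must be >= 0")

    @property
    def chain(self) -> FiberChain:
        return FiberChain.from_beam(
            self.material, self.section, self.beam_length, self.n_particles, self.n_clamped
        )

    @property
    def flexural_rigidity(self) -> float:
        """EI of the aggregate beam, N m^2."""
        return self.material.elastic_modulus * self.section.area_moment

    @property
    def effective_length(self) -> float:
        """Continuum-equivalent cantilever length (n_joints + 1/2) l0."""
        n_joints = self.n_particles - self.n_clamped
        return (n_joints + 0.5) * self.chain.l0


def elastica_deflection(case: CantileverCase, rtol: float = 1.0e-10) -> float:
    """Transverse tip deflection of the inextensible elastica.

    Solves EI theta''(s) = -F cos(theta), theta(0) = 0, theta'(L) = 0
    (clamped rod, dead transverse end load) by shooting on the root
    curvature, then integrates the tip deflection delta = int sin(theta) ds.
    """
    f = case.load
    if f == 0.0:
        return 0.0
    ei = case.flexural_rigidity
    length = case.effective_length
    k = f / ei

    def rhs(_s, y):
        return [y[1], -k * math.cos(y[0]), math.sin(y[0])]

    def shoot(c0):
        sol = solve_ivp(rhs, (0.0, length), [0.0, c0, 0.0], rtol=rtol, atol=1e-14)
        return sol

    def residual(c0):
        return shoot(c0).y[1, -1]

    hi = k * length * 1.0000001  # root curvature cannot exceed F L / EI
    c_star = brentq(residual, 0.0, hi, xtol=1e-14, rtol=8.9e-16)
    return float(shoot(c_star).y[2, -1])


def euler_bernoulli_deflection(case: CantileverCase) -> float:
    """Small-deflection closed form F L^3 / (3 E I)."""
    return case.load * case.effective_length**3 / (3.0 * case.flexural_rigidity)


def _build_cantilever_engine(case: CantileverCase, dt_safety: float = 0.1) -> Engine:
    chain = case.chain
    n = case.n_particles
    # chain hangs along -z from the clamp, as in the brush assembly
    pos = np.zeros((n, 3))
    pos[:, 2] = -np.arange(n) * chain.l0
    clamped = np.arange(n) < case.n_clamped
    bonds = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    joints = np.column_stack([np.arange(n - 2), np.arange(1, n - 1), np.arange(2, n)])
    section = case.section
    mass = case.material.density * section.area * chain.l0
    params = EngineParams(pair_contacts=False, dt_safety=dt_safety)
    return Engine(
        positions=pos,
        masses=np.full(n, mass),
        radius=section.diameter / 2.0,
        clamped=clamped,
        bonds=bonds,
        bond_ks=np.full(n - 1, chain.k_s),
        bond_l0=np.full(n - 1, chain.l0),
        joints=joints,
        joint_kb=np.full(n - 2, chain.k_bend),
        material=case.material,
        params=params,
        tip_indices=np.array([n - 1]),
    )


def dem_cantilever_deflection(case: CantileverCase, tol_force: float = 1.0e-4) -> float:
    """Quasi-static DEM tip deflection: build the 8-particle chain, apply a
    constant-direction (dead) tip load, relax to equilibrium and return the
    tip displacement along the load."""
    if case.load == 0.0:
        return 0.0
    eng = _build_cantilever_engine(case)
    eng.fext[case.n_particles - 1, 0] = case.load
    eng.relax_static(tol_force=tol_force)
    return float(eng.pos[case.n_particles - 1, 0])


def deflection_error_curve(loads, case_kwargs: dict = None) -> pd.DataFrame:
    """Percent error of the DEM deflection vs the elastica over a load sweep.

    Returns a DataFrame with columns load, delta_dem, delta_theory,
    pct_error; a zero load has zero deflection on both sides and is
    excluded from the error column (NaN).  The relaxation is warm-started
    from the previous load for speed and robustness.
    """
    case_kwargs = case_kwargs or {}
    loads = [float(f) for f in loads]
    if any(f < 0 for f in loads):
        raise ValueError("loads must be >= 0")
    base = CantileverCase(load=0.0, **case_kwargs)
    eng = _build_cantilever_engine(base)
    tip = base.n_particles - 1
    done: dict[float, tuple] = {}
    first = True
    for f in sorted(set(loads)):  # duplicates reuse the identical result
        case = CantileverCase(load=f, **case_kwargs)
        if f == 0.0:
            done[f] = (0.0, 0.0, 0.0, np.nan)
            continue
        eng.fext[tip, 0] = f
        eng.relax_static(ramp_steps=5000 if first else 0)
        first = False
        d_dem = float(eng.pos[tip, 0])
        d_th = elastica_deflection(case)
        done[f] = (f, d_dem, d_th, 100.0 * abs(d_dem - d_th) / d_th)
    rows = [done[f] for f in sorted(loads)]
    return pd.DataFrame(rows, columns=["load", "delta_dem", "delta_theory", "pct_error"])
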