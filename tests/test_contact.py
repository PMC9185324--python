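"""Hertz-Mindlin contact law and detection unit tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brushwear.contact import (
    Contact,
    Facet,
    detect_sphere_plane,
    detect_sphere_sphere,
    effective_pair_properties,
    normal_force,
    restitution_beta,
    tangential_force,
)
from brushwear.materials import ACRYLIC, ENAMEL, Material


def pair(e=0.3, mu=0.18, **kw):
    kw.setdefault("radius_a", 0.9e-3)
    kw.setdefault("mass_a", 4.6e-6)
    p = effective_pair_properties(ACRYLIC, ENAMEL, restitution=e, **kw)
    return p


class TestPairProperties:
    def test_identical_materials_symmetry(self):
        """Equal spheres of one material give E* = E/(2(1-nu^2)), R* = R/2,
        m* = m/2."""
        p = effective_pair_properties(ACRYLIC, ACRYLIC, 1e-3, 1e-3, 2e-6, 2e-6)
        e, nu = ACRYLIC.elastic_modulus, ACRYLIC.poisson_ratio
        assert p.eq_elastic_modulus == pytest.approx(e / (2 * (1 - nu**2)), rel=1e-12)
        assert p.eq_radius == pytest.approx(0.5e-3, rel=1e-12)
        assert p.eq_mass == pytest.approx(1e-6, rel=1e-12)

    def test_acrylic_on_enamel_plane(self):
        """Sphere-on-plane E* from the stated closed form; R*, m* from the
        sphere alone."""
        p = effective_pair_properties(ACRYLIC, ENAMEL, 0.9e-3, None, 4.6e-6, None)
        expected = 1.0 / ((1 - 0.09) / 3.4e9 + (1 - 0.09) / 60e9)
        assert p.eq_elastic_modulus == pytest.approx(expected, rel=1e-12)
        assert p.eq_radius == pytest.approx(0.9e-3)
        assert p.eq_mass == pytest.approx(4.6e-6)

    def test_elastic_restitution_no_damping(self):
        assert restitution_beta(1.0) == 0.0
        assert effective_pair_properties(ACRYLIC, ACRYLIC, 1e-3, restitution=1.0).damping_ratio == 0.0

    def test_beta_negative_below_one(self):
        b = restitution_beta(0.3)
        assert b < 0
        ln = math.log(0.3)
        assert b == pytest.approx(ln / math.sqrt(ln**2 + math.pi**2))

    def test_nonphysical_inputs_rejected(self):
        with pytest.raises(ValueError):
            Material("bad", -1.0, 0.3, 1000.0, 1e9)
        with pytest.raises(ValueError):
            Material("bad", 1e9, 0.6, 1000.0, 1e9)
        with pytest.raises(ValueError):
            effective_pair_properties(ACRYLIC, ENAMEL, -1e-3)


class TestNormalForce:
    def test_zero_overlap_zero_force(self):
        assert normal_force(pair(), 0.0, -1.0) == 0.0

    def test_elastic_limit_hertz(self):
        """With e = 1 the damping vanishes: F = (4/3) E* sqrt(R*) d^1.5 for
        any approach speed."""
        p = pair(e=1.0)
        d = 1e-5
        expect = 4.0 / 3.0 * p.eq_elastic_modulus * math.sqrt(p.eq_radius) * d**1.5
        assert normal_force(p, d, -2.0) == pytest.approx(expect, rel=1e-12)

    def test_unit_substitution(self):
        """E* = 1 Pa, R* = 1 m, delta = 1 m, no damping -> 4/3 N."""
        from brushwear.contact import ContactPair

        p = ContactPair(1.0, 1.0, 1.0, 1.0, 0.0, 0.0)
        assert normal_force(p, 1.0) == pytest.approx(4.0 / 3.0)

    def test_negative_overlap_rejected(self):
        with pytest.raises(ValueError):
            normal_force(pair(), -1e-6)

    def test_never_attractive(self):
        # strong separation velocity would make the raw sum negative
        assert normal_force(pair(e=0.1), 1e-6, 100.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(1e-9, 1e-3), st.floats(1e-9, 1e-3))
    def test_monotone_in_overlap(self, d1, d2):
        p = pair()
        lo, hi = sorted((d1, d2))
        assert normal_force(p, lo) <= normal_force(p, hi)


class TestTangentialForce:
    def test_zero_state_zero_force(self):
        f, _ = tangential_force(pair(), 1e-5, np.zeros(3), np.zeros(3))
        assert np.allclose(f, 0.0)

    def test_unit_substitution(self):
        """G* = 1 Pa, R* delta = 1 m^2, delta_t = x, no damping, no cap ->
        F_t = (-8, 0, 0) N."""
        from brushwear.contact import ContactPair

        p = ContactPair(1.0, 1.0, 1.0, 1.0, 0.0, 1e9)
        f, _ = tangential_force(p, 1.0, np.array([1.0, 0.0, 0.0]), np.zeros(3), f_n=1e12)
        assert np.allclose(f, [-8.0, 0.0, 0.0])

    def test_coulomb_cap_and_rescale(self):
        """A large slip saturates |F_t| = mu |F_n| exactly and truncates the
        spring onto the cap."""
        p = pair()
        d = 1e-5
        fn = normal_force(p, d)
        f, dt_new = tangential_force(p, d, np.array([1.0, 0.0, 0.0]), np.zeros(3), f_n=fn)
        assert np.linalg.norm(f) == pytest.approx(p.friction * fn, rel=1e-12)
        f2, _ = tangential_force(p, d, dt_new, np.zeros(3), f_n=fn)
        assert np.allclose(f2, f, rtol=1e-9)

    def test_requires_active_contact(self):
        with pytest.raises(ValueError):
            tangential_force(pair(), 0.0, np.zeros(3), np.zeros(3))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(1e-8, 1e-4),
        st.lists(st.floats(-1e-4, 1e-4), min_size=3, max_size=3),
        st.lists(st.floats(-1.0, 1.0), min_size=3, max_size=3),
    )
    def test_cap_always_respected(self, d, slip, vt):
        p = pair()
        fn = normal_force(p, d)
        f, _ = tangential_force(p, d, np.array(slip), np.array(vt), f_n=fn)
        assert np.linalg.norm(f) <= p.friction * fn * (1 + 1e-9)


class TestDetection:
    def facet(self):
        return Facet(np.array([0.0, 0.0, 0.0]), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]))

    def test_grazing(self):
        c = detect_sphere_plane(np.array([0.5, 0.5, 0.1]), 0.1, self.facet())
        assert c is None or c.delta_n == pytest.approx(0.0)

    def test_half_radius_overlap(self):
        c = detect_sphere_plane(np.array([0.5, 0.5, 0.05]), 0.1, self.facet())
        assert c.delta_n == pytest.approx(0.05)
        assert np.allclose(c.normal, [0, 0, 1])

    def test_outside_bounds(self):
        assert detect_sphere_plane(np.array([1.2, 0.5, 0.01]), 0.1, self.facet()) is None

    def test_edge_contact_normal(self):
        c = detect_sphere_plane(np.array([1.05, 0.5, 0.05]), 0.1, self.facet())
        assert c is not None
        assert np.allclose(c.point, [1.0, 0.5, 0.0])
        assert c.normal[0] > 0 and c.normal[2] > 0

    def test_degenerate_facet_rejected(self):
        with pytest.raises(ValueError):
            Facet(np.zeros(3), np.array([1.0, 0, 0]), np.array([2.0, 0, 0]))

    def test_sphere_sphere_grazing_and_overlap(self):
        r = 1e-3
        assert detect_sphere_sphere(np.zeros(3), r, np.array([2 * r, 0, 0]), r) is None
        c = detect_sphere_sphere(np.zeros(3), r, np.array([1.8 * r, 0, 0]), r)
        assert c.delta_n == pytest.approx(0.2 * r)
        assert np.allclose(c.normal, [-1, 0, 0])

    def test_bonded_pair_excluded(self):
        r = 1e-3
        assert detect_sphere_sphere(np.zeros(3), r, np.array([r, 0, 0]), r, bonded=True) is None

    def test_coincident_centers_rejected(self):
        with pytest.raises(ValueError):
            detect_sphere_sphere(np.zeros(3), 1e-3, np.zeros(3), 1e-3)
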