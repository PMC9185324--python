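"""Assembly, tooth model and stroke kinematics."""

import numpy as np
import pytest

from brushwear.contact import detect_sphere_plane
from brushwear.geometry import (
    FACET_FLOOR,
    FACET_LEFT_PLATE,
    FACET_LEFT_WALL,
    MotionProfile,
    build_brush,
    build_teeth,
    head_position,
    tooth_profile_contacts,
)


class TestBrush:
    def test_counts(self, assembly):
        """42 tufts x 8 particles = 336 particles, 84 clamped."""
        assert assembly.n_chains == 42
        assert assembly.n_particles == 336
        assert int(assembly.clamped.sum()) == 84

    def test_tips_coplanar_and_free_length(self, assembly):
        tips = assembly.positions[assembly.tip_indices]
        assert np.ptp(tips[:, 2]) == 0.0
        # anchor(last clamped)-to-tip distance = 6 bond lengths
        l0 = assembly.chain.l0
        first_free_anchor = assembly.positions[1]
        tip = assembly.positions[7]
        assert np.linalg.norm(tip - first_free_anchor) == pytest.approx(6 * l0)
        # free length = beam length minus the clamped span of one bond
        assert 6 * l0 == pytest.approx(assembly.beam_length - l0)

    def test_anchors_inside_head(self, assembly):
        a = assembly.anchors
        assert np.all(np.abs(a[:, 0]) <= assembly.head_length / 2)
        assert np.all(np.abs(a[:, 1]) <= assembly.head_width / 2)

    def test_mirror_symmetric_grid(self, assembly):
        """The tuft grid is symmetric about the head mid-plane y = 0."""
        ys = np.round(assembly.anchors[:, 1], 12)
        assert set(ys) == set(-ys)

    def test_interpenetrating_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            build_brush(n_cols=20)


class TestTeeth:
    def test_equal_plates_and_span(self, teeth):
        assert teeth.plate_width == pytest.approx((28.0e-3 - 2.4e-3) / 2)
        x0, x1 = teeth.measured_x
        assert x1 - x0 == pytest.approx(28.0e-3)

    def test_facets_coplanar_plates_offset_floor(self, teeth):
        f = teeth.facets()
        for fid in (FACET_LEFT_PLATE,):
            assert np.allclose(f[fid].normal, [0, 0, 1])
        assert f[FACET_LEFT_PLATE].origin[2] == 0.0
        assert f[FACET_FLOOR].origin[2] == pytest.approx(-teeth.groove_depth)
        assert np.allclose(f[FACET_LEFT_WALL].normal, [1, 0, 0])

    def test_groove_wider_than_plates_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            build_teeth(groove_width=20.0e-3)

    def test_unfold_roundtrip(self, teeth):
        u = teeth.unfolded_coord(FACET_FLOOR, teeth.groove_center, -teeth.groove_depth)
        assert u == pytest.approx(teeth.plate_width + teeth.groove_depth + teeth.groove_width / 2)
        assert teeth.unfolded_length == pytest.approx(
            teeth.measured_span + 2 * teeth.groove_depth
        )

    def test_profile_contacts_match_generic_facet_detector(self, teeth, rng):
        """The closed-form profile query agrees with the generic bounded
        facet detector for interior (face) contacts."""
        facets = teeth.facets()
        r = 0.9e-3
        checked = 0
        for _ in range(300):
            c = np.array(
                [
                    rng.uniform(-16e-3, 16e-3),
                    rng.uniform(-6e-3, 6e-3),
                    rng.uniform(-teeth.groove_depth, 2 * r),
                ]
            )
            hits = tooth_profile_contacts(c, r, teeth)
            for delta, normal, point, fid in hits:
                generic = detect_sphere_plane(c, r, facets[fid])
                if generic is None:
                    continue  # generic facet may be grazing at the boundary
                if np.allclose(generic.normal, facets[fid].normal):
                    assert delta == pytest.approx(generic.delta_n, abs=1e-12)
                    assert np.allclose(normal, generic.normal)
                    checked += 1
        assert checked > 50

    def test_profile_no_double_count_at_corner(self, teeth):
        """A sphere over the convex plate/wall corner yields one contact."""
        r = 0.9e-3
        c = np.array([teeth.groove_left - 0.2e-3, 0.0, 0.5 * r])
        hits = tooth_profile_contacts(c, r, teeth)
        assert len(hits) == 1

    def test_profile_two_contacts_in_concave_corner(self, teeth):
        r = 0.9e-3
        c = np.array(
            [teeth.groove_left + 0.7 * r, 0.0, -teeth.groove_depth + 0.7 * r]
        )
        hits = tooth_profile_contacts(c, r, teeth)
        assert len(hits) == 2
        fids = {h[3] for h in hits}
        assert fids == {FACET_LEFT_WALL, FACET_FLOOR}


class TestMotion:
    def test_displacement_profile(self):
        m = MotionProfile(speed=0.05, depth=0.9e-3, stroke=56e-3)
        assert m.duration == pytest.approx(1.12)
        assert head_position(0.0, m) == (0.0, 0.05)
        s, v = head_position(m.turnaround, m)
        assert s == pytest.approx(28e-3)
        s_end, v_end = head_position(m.duration, m)
        assert s_end == pytest.approx(0.0, abs=1e-12)
        assert v_end == -0.05

    def test_continuity_at_reversal(self):
        m = MotionProfile(speed=0.1, depth=0.9e-3, stroke=56e-3)
        eps = 1e-9
        s1, _ = head_position(m.turnaround - eps, m)
        s2, _ = head_position(m.turnaround + eps, m)
        assert s1 == pytest.approx(s2, abs=1e-9)

    def test_out_of_window_rejected(self):
        m = MotionProfile(speed=0.1, depth=0.9e-3, stroke=56e-3)
        with pytest.raises(ValueError):
            head_position(-0.1, m)
        with pytest.raises(ValueError):
            head_position(m.duration + 0.1, m)

    def test_groove_crossings_at_stroke_fifths(self, teeth):
        """Head center crosses the groove midline after travelling L/5
        (forward) and at total distance 4L/5 (backward)."""
        m = MotionProfile(speed=0.1, depth=0.9e-3, stroke=56e-3)
        start = m.start_center(teeth.groove_center)
        t1, t2 = m.crossing_times()
        assert m.speed * t1 == pytest.approx(0.2 * m.stroke)
        s1, _ = head_position(t1, m)
        s2, _ = head_position(t2, m)
        assert start + s1 == pytest.approx(teeth.groove_center)
        assert start + s2 == pytest.approx(teeth.groove_center)

    def test_head_height_sets_tip_overlap(self):
        m = MotionProfile(speed=0.1, depth=0.45e-3, stroke=56e-3)
        z = m.head_height(0.9e-3, 10.8e-3)
        tip_z = z - 10.8e-3
        assert 0.9e-3 - tip_z == pytest.approx(m.depth)
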