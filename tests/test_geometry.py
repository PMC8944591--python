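"""Eye-pair construction, binocular queries, tiling, and flow fields."""

import numpy as np
import pytest

from saccadeye.geometry import (GeometryConfig, GeometryError, build_eye_pair,
                                binocular_pairs, coverage_count, rf_tiling,
                                tiling_gap_fraction, optic_flow_field,
                                microsaccade_direction_map, flow_match_error,
                                load_vector_map, angular_distance_deg,
                                sph_to_unit)


class TestLattice:
    def test_mirror_symmetry(self, eye_pair):
        """Every left ommatidium has a right twin at mirrored azimuth."""
        assert np.array_equal(eye_pair.left.az, -eye_pair.right.az)
        assert np.array_equal(eye_pair.left.el, eye_pair.right.el)
        assert np.array_equal(eye_pair.left.saccade_axis[:, 0],
                              -eye_pair.right.saccade_axis[:, 0])
        assert np.array_equal(eye_pair.left.saccade_axis[:, 1],
                              eye_pair.right.saccade_axis[:, 1])

    def test_ommatidium_count_near_880(self, eye_pair):
        assert 840 <= eye_pair.right.n_ommatidia <= 920

    def test_neighbor_relation_symmetric_and_spaced(self, eye_pair):
        eye = eye_pair.right
        dphi = eye_pair.config.interommatidial_deg
        for i in range(0, eye.n_ommatidia, 37):
            for j in eye.neighbors[i]:
                assert i in eye.neighbors[j]
                d = angular_distance_deg(eye.az[i], eye.el[i], eye.az[j], eye.el[j])
                assert abs(d - dphi) < 0.1 * dphi

    def test_r7_r8_share_axis_r1_r6_distinct(self, eye_pair):
        spec = eye_pair.right.ommatidium(0)
        assert np.array_equal(spec.photoreceptor_offsets[6],
                              spec.photoreceptor_offsets[7])
        ring = spec.photoreceptor_offsets[:6]
        assert len({tuple(np.round(r, 9)) for r in ring}) == 6

    def test_equatorial_symmetry_of_offsets(self, eye_pair):
        eye = eye_pair.right
        up = np.where(eye.el > 0)[0][0]
        dn = eye.nearest_ommatidium(eye.az[up], -eye.el[up])
        assert np.allclose(eye.pr_offsets[up][:, 1], -eye.pr_offsets[dn][:, 1])

    def test_double_spacing_quarters_count(self, eye_pair):
        """Halving angular resolution should quarter the ommatidium count."""
        coarse = build_eye_pair(GeometryConfig(interommatidial_deg=9.0))
        ratio = coarse.right.n_ommatidia / eye_pair.right.n_ommatidia
        assert 0.19 < ratio < 0.33

    @pytest.mark.parametrize("bad", [
        dict(interommatidial_deg=0.0),
        dict(interommatidial_deg=-1.0),
        dict(baseline_mm=0.0),
        dict(field_az_deg=(10.0, 10.0)),
    ])
    def test_invalid_config_raises(self, bad):
        with pytest.raises(GeometryError):
            build_eye_pair(GeometryConfig(**bad))

    def test_superposition_pools_seven_ommatidia(self, eye_pair):
        """Away from the lattice edge a cartridge pools 7 ommatidia."""
        eye = eye_pair.right
        c = eye.nearest_ommatidium(20.0, 0.0)
        members = eye.cartridges[c]
        assert len(members) == 8  # resident R7/R8 + one R1-R6 per neighbor
        assert len({o for o, _ in members}) == 7

    def test_binocular_region_extent(self, eye_pair):
        (az_lo, az_hi), (el_lo, el_hi) = eye_pair.binocular_region
        assert az_hi - az_lo == pytest.approx(23.5)
        assert el_hi - el_lo > 160.0


class TestBinocular:
    def test_frontal_coverage_at_least_16(self, eye_pair):
        """A frontal point at 25 mm falls in >= 16 receptive fields."""
        assert coverage_count(eye_pair, (0.0, 0.0), 25.0) >= 16

    def test_lateral_monocular_coverage_at_least_8(self, eye_pair):
        """A lateral point is seen by the superposed R1-R6 + R7/R8 set."""
        assert coverage_count(eye_pair, (60.0, 0.0), 25.0) >= 8

    def test_point_behind_head_not_covered(self, eye_pair):
        assert coverage_count(eye_pair, (180.0, 0.0), 25.0) == 0

    def test_coverage_invariant_under_azimuth_flip(self, eye_pair):
        for az, el in ((4.0, 2.0), (8.0, -5.0), (1.3, 0.7)):
            assert coverage_count(eye_pair, (az, el), 25.0) == \
                coverage_count(eye_pair, (-az, el), 25.0)

    def test_pairs_have_overlapping_rfs(self, eye_pair):
        pairs = binocular_pairs(eye_pair)
        assert pairs
        laz, lel = eye_pair.left.pr_centers()
        raz, rel = eye_pair.right.pr_centers()
        for (lo, lp), (ro, rp) in pairs[::50]:
            sep = angular_distance_deg(laz[lo, lp], lel[lo, lp],
                                       raz[ro, rp], rel[ro, rp])
            halfsum = (eye_pair.left.pr_fwhm[lo, lp]
                       + eye_pair.right.pr_fwhm[ro, rp]) / 2.0
            assert sep < halfsum

    def test_empty_binocular_region_gives_no_pairs(self):
        pair = build_eye_pair(GeometryConfig(binocular_az_deg=0.0))
        assert binocular_pairs(pair) == []

    def test_frontal_strip_fully_paired(self, eye_pair):
        """Every direction in the frontal +/-10 deg strip has a pair."""
        pairs = binocular_pairs(eye_pair)
        laz, lel = eye_pair.left.pr_centers()
        centers = np.array([[laz[lo, lp], lel[lo, lp]] for (lo, lp), _ in pairs])
        half = eye_pair.config.rf_fwhm_deg / 2.0
        for az in np.linspace(-10, 10, 21):
            for el in np.linspace(-10, 10, 11):
                d = np.hypot(centers[:, 0] - az, centers[:, 1] - el)
                assert d.min() < half, f"no pair covers ({az},{el})"

    def test_corresponding_crossed_axes_intersect_in_front(self, eye_pair):
        """Crossed frontal R6 axes converge at a point in front of the head."""
        left = eye_pair.left
        i = left.nearest_ommatidium(4.5, 0.0)  # left eye looking rightward
        az_l = left.az[i] + left.pr_offsets[i, 5, 0]
        az_r = eye_pair.right.az[i] + eye_pair.right.pr_offsets[i, 5, 0]
        # 2D ray intersection oracle in the horizontal plane (x right, y fwd)
        pl, dl = left.position_mm[:2], np.array([np.sin(np.deg2rad(az_l)),
                                                 np.cos(np.deg2rad(az_l))])
        pr, dr = eye_pair.right.position_mm[:2], np.array(
            [np.sin(np.deg2rad(az_r)), np.cos(np.deg2rad(az_r))])
        A = np.array([dl, -dr]).T
        t, s = np.linalg.solve(A, pr - pl)
        meet = pl + t * dl
        assert t > 0 and s > 0 and meet[1] > 0

    def test_pair_projection_consistent_with_baseline(self, eye_pair):
        """Near-parallel pairs project ~one baseline apart at any depth."""
        pairs = binocular_pairs(eye_pair)
        laz, _ = eye_pair.left.pr_centers()
        raz, _ = eye_pair.right.pr_centers()
        depth = 25.0
        checked = 0
        for (lo, lp), (ro, rp) in pairs:
            if abs(laz[lo, lp] - raz[ro, rp]) < 0.05:
                xl = -eye_pair.baseline_mm / 2 + depth * np.tan(np.deg2rad(laz[lo, lp]))
                xr = eye_pair.baseline_mm / 2 + depth * np.tan(np.deg2rad(raz[ro, rp]))
                assert abs((xr - xl) - eye_pair.baseline_mm) < depth * np.tan(np.deg2rad(0.05))
                checked += 1
        assert checked > 0


class TestTiling:
    @pytest.mark.parametrize("depth", [5.0, 50.0, 200.0])
    def test_frontal_window_completely_tiled(self, eye_pair, depth):
        proj = rf_tiling(eye_pair, depth)
        w = depth * np.tan(np.deg2rad(10.0))
        assert tiling_gap_fraction(proj, (-w, w, -w, w)) == 0.0

    def test_footprints_scale_linearly_with_depth(self, eye_pair):
        near = rf_tiling(eye_pair, 50.0)
        far = rf_tiling(eye_pair, 100.0)
        assert np.allclose(far.radii_mm, 2.0 * near.radii_mm, rtol=1e-9)
        assert np.allclose(far.centers_mm, 2.0 * near.centers_mm
                           + np.stack([np.where(far.eye == "left", -1, 1)
                                       * -eye_pair.baseline_mm / 2,
                                       np.zeros(far.eye.size)], axis=-1), atol=1e-6)

    def test_single_ommatidium_leaves_gaps(self, eye_pair):
        omm = eye_pair.right.nearest_ommatidium(0.0, 0.0)
        proj = rf_tiling(eye_pair, 25.0, subset=[("right", omm)])
        w = 25.0 * np.tan(np.deg2rad(10.0))
        assert tiling_gap_fraction(proj, (-w, w, -w, w)) > 0.1

    def test_nonpositive_depth_rejected(self, eye_pair):
        with pytest.raises(GeometryError):
            rf_tiling(eye_pair, 0.0)


class TestOpticFlow:
    def test_translation_pole_and_equator(self):
        az = np.array([0.0, 90.0, -90.0])
        el = np.zeros(3)
        f = optic_flow_field([0, 1, 0], [0, 0, 0], az, el)
        assert f.magnitude[0] == pytest.approx(0.0, abs=1e-12)  # focus
        assert f.magnitude[1] == pytest.approx(1.0)  # 90 deg off heading
        # lateral flow points front-to-back (positive azimuth on the right)
        assert f.vectors[1, 0] == pytest.approx(1.0)
        assert f.vectors[2, 0] == pytest.approx(-1.0)

    def test_closed_form_tangential_projection(self, rng):
        az = rng.uniform(-150, 150, 40)
        el = rng.uniform(-80, 80, 40)
        t = np.array([0.3, 0.8, -0.2])
        f = optic_flow_field(t, [0, 0, 0], az, el)
        r = sph_to_unit(az, el)
        v = (r @ t)[:, None] * r - t  # tangential projection of -t
        expect = np.linalg.norm(v - (np.sum(v * r, axis=1)[:, None]) * r, axis=1)
        assert np.allclose(f.magnitude, expect, atol=1e-12)
        # magnitude proportional to sin(angle to heading)
        sin_ang = np.linalg.norm(np.cross(r, t / np.linalg.norm(t)), axis=1)
        assert np.allclose(f.magnitude, np.linalg.norm(t) * sin_ang, atol=1e-9)

    def test_pure_yaw_equatorial_vectors_horizontal(self):
        az = np.linspace(-120, 120, 13)
        f = optic_flow_field([0, 0, 0], [0, 0, 1.0], az, np.zeros_like(az))
        assert np.allclose(f.vectors[:, 1], 0.0, atol=1e-12)
        assert np.all(f.vectors[:, 0] == f.vectors[0, 0])  # same handedness

    def test_zero_motion_flagged_as_zero_field(self):
        f = optic_flow_field([0, 0, 0], [0, 0, 0], np.array([10.0]), np.array([0.0]))
        assert f.magnitude[0] == 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(GeometryError):
            optic_flow_field([0, 1, 0], [0, 0, 0], np.array([]), np.array([]))


class TestDirectionMaps:
    def test_map_equals_mirror_under_azimuth_flip(self, eye_pair):
        m = microsaccade_direction_map(eye_pair)
        mm = m.mirrored()
        order = np.lexsort((m.el, m.az, m.eye))
        order_m = np.lexsort((mm.el, mm.az, mm.eye))
        assert np.allclose(m.vectors[order], mm.vectors[order_m])
        assert np.array_equal(m.eye[order], mm.eye[order_m])

    def test_fast_phase_tracks_forward_flow(self, eye_pair):
        """Median angular error against forward-translation flow is small."""
        m = microsaccade_direction_map(eye_pair, phase="fast")
        flow = optic_flow_field([0, 1, 0], [0, 0, 0], m.az, m.el)
        err = flow_match_error(m, flow)
        assert err["median_deg"] < 30.0

    def test_flow_match_error_extremes(self, eye_pair):
        m = microsaccade_direction_map(eye_pair)
        same = flow_match_error(m, m)
        assert np.allclose(same["error_deg"], 0.0)
        neg = flow_match_error(m, type(m)(az=m.az, el=m.el, vectors=-m.vectors,
                                          magnitude=m.magnitude))
        assert np.allclose(neg["error_deg"], 180.0)
        orth = type(m)(az=m.az, el=m.el,
                       vectors=np.stack([-m.vectors[:, 1], m.vectors[:, 0]], axis=-1),
                       magnitude=m.magnitude)
        assert np.allclose(flow_match_error(m, orth)["error_deg"], 90.0)

    def test_grid_mismatch_rejected(self, eye_pair):
        m = microsaccade_direction_map(eye_pair)
        other = type(m)(az=m.az + 1.0, el=m.el, vectors=m.vectors)
        with pytest.raises(GeometryError):
            flow_match_error(m, other)

    def test_csv_map_normalized_on_load(self, tmp_path):
        path = tmp_path / "map.csv"
        path.write_text("azimuth_deg,elevation_deg,vx,vy,eye\n"
                        "10,0,2.0,0.0,left\n-10,0,0.0,-3.0,right\n")
        m = load_vector_map(path)
        assert np.allclose(np.linalg.norm(m.vectors, axis=1), 1.0)

    def test_malformed_csv_names_offending_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("azimuth_deg,elevation_deg,vx,vy,eye\n"
                        "10,0,1.0,0.0,left\n-10,0,0.0,0.0,right\n")
        with pytest.raises(GeometryError, match="row 1"):
            load_vector_map(path)
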