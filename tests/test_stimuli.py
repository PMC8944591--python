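"""Scene construction and binocular rendering."""

import numpy as np
import pytest

from saccadeye.kinematics import KineticsParams
from saccadeye.stimuli import (Dot, Grating, Pin, Scene, SceneError,
                               make_dot_pair, make_hidden_dot_scene,
                               render_binocular, rasterize, mirror_scene,
                               frontal_subset, _dot_view)


@pytest.fixture(scope="module")
def subset(eye_pair):
    return frontal_subset(eye_pair, az_extent_deg=10.0, el_extent_deg=5.0)


class TestSceneFactories:
    def test_dot_pair_separation(self):
        """When the lead dot crosses azimuth 0 the trailing one is -3.5 deg."""
        scene = make_dot_pair()
        lead, trail = scene.objects
        t_cross = -1000.0 * lead.az_deg / lead.speed_dps
        assert lead.azimuth_at(t_cross) == pytest.approx(0.0)
        assert trail.azimuth_at(t_cross) == pytest.approx(-3.5)

    def test_zero_speed_is_static(self, eye_pair):
        scene = make_dot_pair(speed_dps=0.0)
        d = scene.objects[0]
        assert d.azimuth_at(0.0) == d.azimuth_at(200.0)

    def test_metric_size_doubles_with_depth(self):
        near = Dot(az_deg=0, diameter_deg=2.0, depth_mm=25.0)
        far = Dot(az_deg=0, diameter_deg=2.0, depth_mm=50.0)
        r_near = near.depth_mm * np.tan(np.deg2rad(1.0))
        r_far = far.depth_mm * np.tan(np.deg2rad(1.0))
        assert r_far == pytest.approx(2 * r_near)

    def test_hidden_dot_scene_and_control(self):
        scene, ctrl = make_hidden_dot_scene()
        grid = np.arange(-6, 6, 0.05)
        img = rasterize(scene, grid, grid)
        img_ctrl = rasterize(ctrl, grid, grid)
        assert img_ctrl.max() - img_ctrl.min() == pytest.approx(1.0)  # full contrast
        # removing the dot recovers the control exactly
        dotless = Scene(objects=[o for o in scene.objects if isinstance(o, Grating)],
                        background=scene.background)
        assert np.array_equal(rasterize(dotless, grid, grid), img_ctrl)
        assert not np.array_equal(img, img_ctrl)

    @pytest.mark.parametrize("pos", [-2.4, 0.0, 2.4])
    def test_hidden_dot_positions_representable(self, pos):
        scene, _ = make_hidden_dot_scene(dot_position_deg=pos)
        dot = [o for o in scene.objects if isinstance(o, Dot)][0]
        assert dot.az_deg == pytest.approx(pos)
        # the dot is centered on a white stripe
        grid = np.arange(pos - 0.5, pos + 0.5, 0.02)
        ctrl = rasterize(scene, np.array([pos]), np.array([5.0]))
        assert ctrl[0, 0] == 1.0

    def test_scene_file_roundtrip(self, tmp_path):
        from saccadeye.stimuli import load_scene
        path = tmp_path / "scene.yaml"
        path.write_text(
            "background: 1.0\nduration_ms: 200\n"
            "objects:\n"
            "  - {type: dot, az_deg: -5.0, depth_mm: 25.0, diameter_deg: 1.7,\n"
            "     speed_dps: 50.0}\n"
            "  - {type: grating, wavelength_deg: 9.0, drift_dps: 20.0}\n")
        scene = load_scene(path)
        assert isinstance(scene.objects[0], Dot)
        assert isinstance(scene.objects[1], Grating)
        assert scene.objects[0].speed_dps == 50.0

    def test_scene_file_unknown_type_rejected(self, tmp_path):
        from saccadeye.stimuli import load_scene
        path = tmp_path / "bad.yaml"
        path.write_text("objects:\n  - {type: blob}\n")
        with pytest.raises(SceneError, match="blob"):
            load_scene(path)

    def test_invalid_scene_rejected(self):
        with pytest.raises(SceneError):
            make_dot_pair(separation_deg=-1.0)
        with pytest.raises(SceneError):
            Scene(objects=[Dot(az_deg=0, luminance=2.0)]).validate()
        with pytest.raises(SceneError):
            Scene(objects=[], dt_ms=2.0).validate()


class TestPerspective:
    @pytest.mark.parametrize("depth,expected", [(25.0, 0.9167129), (100.0, 0.2291828)])
    def test_disparity_matches_closed_form(self, eye_pair, depth, expected):
        """Inter-eye azimuth difference equals 2*atan(k/2z) exactly."""
        dot = Dot(az_deg=0.0, depth_mm=depth)
        az_l, _, _ = _dot_view(dot, 0.0, eye_pair.left.position_mm)
        az_r, _, _ = _dot_view(dot, 0.0, eye_pair.right.position_mm)
        closed = 2 * np.rad2deg(np.arctan(eye_pair.baseline_mm / (2 * depth)))
        assert az_l - az_r == pytest.approx(closed, rel=1e-9)
        assert az_l - az_r == pytest.approx(expected, abs=1e-6)

    def test_disparity_decays_inversely_with_depth(self, eye_pair):
        z = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        disp = []
        for depth in z:
            dot = Dot(az_deg=0.0, depth_mm=depth)
            al, _, _ = _dot_view(dot, 0.0, eye_pair.left.position_mm)
            ar, _, _ = _dot_view(dot, 0.0, eye_pair.right.position_mm)
            disp.append(al - ar)
        assert np.allclose(disp, 2 * np.rad2deg(np.arctan(0.4 / (2 * z))), rtol=1e-9)


class TestRendering:
    def test_uniform_scene_constant_intensity_zero_offsets(self, eye_pair, subset):
        scene = Scene(objects=[], background=0.7, duration_ms=120.0)
        for mode in ("static", "microsaccadic"):
            li = render_binocular(scene, eye_pair, mode=mode, subset=subset)
            assert np.allclose(li.intensity, 0.7)
            # constant light still drives a tonic contraction, but uniform
            # scenes leave the rendered intensities flat
            assert np.ptp(li.intensity) == 0.0

    def test_noise_free_rendering_deterministic(self, eye_pair, subset):
        scene = make_dot_pair(start_az_deg=-8, end_az_deg=2)
        a = render_binocular(scene, eye_pair, KineticsParams(), "microsaccadic",
                             subset=subset)
        b = render_binocular(scene, eye_pair, KineticsParams(), "microsaccadic",
                             subset=subset)
        assert np.array_equal(a.intensity, b.intensity)

    def test_poisson_rendering_reproducible_by_seed(self, eye_pair, subset):
        scene = make_dot_pair(start_az_deg=-8, end_az_deg=2)
        a = render_binocular(scene, eye_pair, mode="static", subset=subset,
                             seed=5, photon_rate_per_ms=100.0)
        b = render_binocular(scene, eye_pair, mode="static", subset=subset,
                             seed=5, photon_rate_per_ms=100.0)
        c = render_binocular(scene, eye_pair, mode="static", subset=subset,
                             seed=6, photon_rate_per_ms=100.0)
        assert np.array_equal(a.intensity, b.intensity)
        assert not np.array_equal(a.intensity, c.intensity)

    def test_mirror_equivariance_bit_exact(self, eye_pair, subset):
        """Mirrored scene + eye swap reproduces the rendering bit-for-bit."""
        scene = make_dot_pair(depth_mm=25.0, start_az_deg=-10, end_az_deg=6)
        mirrored = mirror_scene(scene)
        for mode in ("static", "microsaccadic"):
            orig = render_binocular(scene, eye_pair, KineticsParams(), mode,
                                    subset=subset)
            mirr = render_binocular(mirrored, eye_pair, KineticsParams(), mode,
                                    subset=subset)
            for side, other in (("left", "right"), ("right", "left")):
                sel = orig.eye == side
                for row in np.where(sel)[0][::7]:
                    o, p = orig.omm[row], orig.pr[row]
                    twin = mirr.row(other, o, p)
                    assert np.array_equal(orig.intensity[row], mirr.intensity[twin])

    def test_monocular_zeroes_one_eye(self, eye_pair, subset):
        scene = make_dot_pair(start_az_deg=-8, end_az_deg=2)
        li = render_binocular(scene, eye_pair, mode="monocular", subset=subset,
                              monocular_side="right")
        assert np.all(li.intensity[li.eye == "left"] == 0.0)
        assert np.any(li.intensity[li.eye == "right"] > 0.0)
        with pytest.raises(SceneError):
            render_binocular(scene, eye_pair, mode="monocular", subset=subset,
                             monocular_side="both")

    def test_pin_renders_as_depth_stack(self, eye_pair, subset):
        pin = Pin(base=Dot(az_deg=0.0, depth_mm=25.0, diameter_deg=1.0))
        segs = pin.segments()
        assert len(segs) == pin.n_segments
        assert segs[-1].depth_mm == pytest.approx(21.0)
        scene = Scene(objects=[pin], duration_ms=50.0)
        li = render_binocular(scene, eye_pair, mode="static", subset=subset)
        assert li.intensity.min() < 1.0

    def test_hdf5_roundtrip(self, eye_pair, subset, tmp_path):
        scene = make_dot_pair(start_az_deg=-8, end_az_deg=0)
        li = render_binocular(scene, eye_pair, mode="static", subset=subset, seed=9)
        path = tmp_path / "light.h5"
        li.to_hdf5(path)
        back = type(li).from_hdf5(path)
        assert np.array_equal(back.intensity, li.intensity)
        assert back.seed == 9
        assert np.array_equal(back.omm, li.omm)
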