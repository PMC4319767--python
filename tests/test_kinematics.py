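"""Signal primitives and geometric variables."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from epannot import (
    ConfigError,
    DataError,
    StimulusGeometry,
    ThresholdConfig,
    central_rate,
    detect_lift,
    extract_features,
    hull_size,
    lowpass_filter,
    midpoint,
    orientation_angle,
    point_in_stimulus,
    relative_speed,
    stimulus_corners,
    surface_distance,
    render_scenario,
    ep_scenario,
)
from .conftest import box_distance_oracle

FS = 300.0
IDENT = np.array([1.0, 0.0, 0.0, 0.0])


def _amp_ratio(cutoff, f, order=2, fs=FS):
    t = np.arange(int(4 * fs)) / fs
    x = np.sin(2 * np.pi * f * t)
    y = lowpass_filter(x, fs, cutoff, order)
    core = slice(int(fs), int(3 * fs))  # steady-state stretch
    return np.abs(y[core]).max() / np.abs(x[core]).max()


class TestLowpass:
    def test_constant_series_unchanged(self):
        x = np.full(1000, 3.7)
        np.testing.assert_allclose(lowpass_filter(x, FS, 6.0, 2), x, atol=1e-9)

    def test_two_pass_gain_at_cutoff_is_half(self):
        """Forward-backward filtering squares the -3 dB point: gain ~0.5 at 6 Hz."""
        assert _amp_ratio(6.0, 6.0) == pytest.approx(0.5, abs=0.05)

    def test_passband_transparent(self):
        assert _amp_ratio(6.0, 0.5) > 0.99

    def test_zero_phase(self):
        t = np.arange(int(4 * FS)) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        y = lowpass_filter(x, FS, 6.0, 2)
        core = slice(int(FS), int(3 * FS))
        # zero-lag cross-correlation is maximal: no phase delay
        lags = range(-5, 6)
        cors = [np.dot(np.roll(y, lag)[core], x[core]) for lag in lags]
        assert lags[int(np.argmax(cors))] == 0

    def test_errors(self):
        with pytest.raises(ValueError):
            lowpass_filter(np.zeros(5), FS, 6.0, 2)
        with pytest.raises(ConfigError):
            lowpass_filter(np.zeros(100), FS, 200.0, 2)


class TestCentralRate:
    def test_linear_ramp_exact(self):
        x = 2.5 * np.arange(50) / FS
        np.testing.assert_allclose(central_rate(x, FS), 2.5, atol=1e-9)

    def test_constant_zero(self):
        np.testing.assert_allclose(central_rate(np.full(30, 9.9), FS), 0.0, atol=1e-12)

    def test_sinusoid_error_within_taylor_bound(self):
        f = 2.0
        t = np.arange(300) / FS
        x = np.sin(2 * np.pi * f * t)
        rate = central_rate(x, FS)
        exact = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        bound = (2 * np.pi * f / FS) ** 2 / 6 * 2 * np.pi * f
        assert np.abs(rate[1:-1] - exact[1:-1]).max() < bound

    def test_too_short(self):
        with pytest.raises(ValueError):
            central_rate(np.zeros(2), FS)


class TestRelativeSpeed:
    def test_static_zero(self):
        p = np.tile([100.0, 0.0, 0.0], (60, 1))
        s = np.zeros((60, 3))
        np.testing.assert_allclose(relative_speed(p, s, FS), 0.0, atol=1e-12)

    def test_radial_recession_matches_speed(self):
        t = np.arange(60) / FS
        p = np.column_stack([50.0 + 100.0 * t, np.zeros(60), np.zeros(60)])
        s = np.zeros((60, 3))
        v = relative_speed(p, s, FS)  # 100 mm/s = 0.1 m/s
        np.testing.assert_allclose(v[1:-1], 0.1, atol=1e-3)

    def test_circling_reads_zero_range_rate(self):
        t = np.arange(120) / FS
        theta = 2 * np.pi * 2.0 * t
        p = np.column_stack([80 * np.cos(theta), 80 * np.sin(theta), np.zeros_like(t)])
        s = np.zeros((120, 3))
        v = relative_speed(p, s, FS)
        assert np.abs(v).max() < 1e-6  # range rate blind to tangential motion
        v2 = relative_speed(p, s, FS, mode="velocity_norm")
        assert v2[10] == pytest.approx(80 * 2 * np.pi * 2.0 / 1000, rel=1e-3)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            relative_speed(np.zeros((5, 3)), np.zeros((6, 3)), FS)


class TestStimulusGeometryOps:
    def test_identity_pose_corners(self, geom):
        corners = stimulus_corners(np.zeros(3), IDENT, geom)
        expect = {(sx * 26.0, sy * 31.0, sz * 60.0)
                  for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)}
        assert {tuple(np.round(c, 9)) for c in corners} == expect

    def test_yaw_quarter_turn_swaps_extents(self, geom):
        q = np.array([np.cos(np.pi / 4), 0.0, 0.0, np.sin(np.pi / 4)])  # 90 deg yaw
        corners = stimulus_corners(np.zeros(3), q, geom)
        assert np.ptp(corners[:, 0]) == pytest.approx(62.0, abs=1e-9)
        assert np.ptp(corners[:, 1]) == pytest.approx(52.0, abs=1e-9)

    def test_corner_centroid_is_sensor_position(self, geom):
        rng = np.random.default_rng(7)
        for _ in range(20):
            pos = rng.uniform(-100, 100, 3)
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            corners = stimulus_corners(pos, q, geom)
            np.testing.assert_allclose(corners.mean(axis=0), pos, atol=1e-9)

    def test_non_unit_quaternion_rejected(self, geom):
        with pytest.raises(DataError):
            stimulus_corners(np.zeros(3), np.array([1.0, 0.1, 0.0, 0.0]), geom)


class TestHullSize:
    def test_interior_thumb_gives_cuboid_volume(self, geom):
        corners = stimulus_corners(np.zeros(3), IDENT, geom)
        assert hull_size(corners, np.zeros(3)) == pytest.approx(386_880.0, rel=1e-12)

    def test_thumb_above_top_face_adds_pyramid(self, geom):
        """30 mm above the 52x62 top face center: + (1/3)*52*62*30 mm^3."""
        corners = stimulus_corners(np.zeros(3), IDENT, geom)
        vol = hull_size(corners, np.array([0.0, 0.0, 90.0]))
        assert vol == pytest.approx(386_880.0 + 52 * 62 * 30 / 3, rel=1e-9)
        assert vol == pytest.approx(419_120.0, rel=1e-9)

    def test_thumb_on_face_adds_nothing(self, geom):
        corners = stimulus_corners(np.zeros(3), IDENT, geom)
        assert hull_size(corners, np.array([26.0, 0.0, 0.0])) == pytest.approx(
            386_880.0, rel=1e-12
        )

    def test_hull_at_least_cuboid_iff_outside(self, geom):
        """hull >= volume always; equality exactly when the thumb is inside."""
        rng = np.random.default_rng(11)
        corners = stimulus_corners(np.zeros(3), IDENT, geom)
        for _ in range(50):
            thumb = rng.uniform(-80, 80, 3)
            vol = hull_size(corners, thumb)
            inside = point_in_stimulus(thumb, np.zeros(3), IDENT, geom)
            assert vol >= geom.volume_mm3 - 1e-6
            if inside:
                assert vol == pytest.approx(geom.volume_mm3, rel=1e-9)
            else:
                assert vol > geom.volume_mm3 + 1e-6

    def test_degenerate_points_rejected(self):
        flat = np.zeros((8, 3))
        with pytest.raises(DataError):
            hull_size(flat, np.zeros(3))


class TestSurfaceDistance:
    def test_face_center_on_grid(self, geom):
        assert surface_distance(np.array([26.0, 0, 0]), np.zeros(3), IDENT, geom) == 0.0

    def test_along_outward_normal(self, geom):
        d = surface_distance(np.array([46.0, 0, 0]), np.zeros(3), IDENT, geom)
        assert d == pytest.approx(20.0, abs=1e-9)

    def test_center_sees_half_smallest_dimension(self, geom):
        d = surface_distance(np.zeros(3), np.zeros(3), IDENT, geom)
        assert d == pytest.approx(26.0, abs=1e-9)

    def test_pose_invariance(self, geom):
        rng = np.random.default_rng(3)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        pos = rng.uniform(-50, 50, 3)
        local = np.array([40.0, -10.0, 30.0])
        world = pos + Rotation.from_quat(np.roll(q, -1)).apply(local)
        d_posed = surface_distance(world, pos, q, geom)
        d_canon = surface_distance(local, np.zeros(3), IDENT, geom)
        assert d_posed == pytest.approx(d_canon, abs=1e-9)

    def test_grid_overestimates_true_distance_within_half_pitch(self, geom):
        rng = np.random.default_rng(5)
        bound = geom.max_grid_gap_mm((5, 9))
        for _ in range(50):
            p = rng.uniform(-120, 120, 3)
            d_grid = surface_distance(p, np.zeros(3), IDENT, geom)
            d_true = box_distance_oracle(p, geom)
            assert d_grid >= d_true - 1e-9
            assert d_grid <= d_true + bound + 1e-9


class TestPointInStimulus:
    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0, 0, 0), True),
            ((1000.0, 0, 0), False),
            ((26.0, 0, 0), True),  # closed box: on-face counts as inside
            ((26.0001, 0, 0), False),
        ],
    )
    def test_containment(self, geom, point, expected):
        assert point_in_stimulus(np.array(point, float), np.zeros(3), IDENT, geom) is expected


class TestMidpointAndAngle:
    def test_midpoint(self):
        np.testing.assert_allclose(
            midpoint(np.zeros(3), np.array([10.0, 0, 0])), [5.0, 0, 0]
        )
        p = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(midpoint(p, p), p)
        np.testing.assert_allclose(
            midpoint(p, np.array([4.0, 5, 6])), midpoint(np.array([4.0, 5, 6]), p)
        )

    def test_equal_orientations_zero(self):
        q = np.array([np.cos(0.3), np.sin(0.3), 0, 0])
        assert orientation_angle(q, q) == pytest.approx(0.0, abs=1e-9)

    def test_quarter_turn_is_90(self):
        q90 = np.array([np.cos(np.pi / 4), 0, np.sin(np.pi / 4), 0])
        assert orientation_angle(IDENT, q90) == pytest.approx(90.0, abs=1e-9)

    def test_symmetry_and_sign_insensitivity(self):
        """Matches the rotation-matrix trace formula; q and -q identical."""
        rng = np.random.default_rng(13)
        for _ in range(25):
            q1, q2 = rng.normal(size=(2, 4))
            q1 /= np.linalg.norm(q1)
            q2 /= np.linalg.norm(q2)
            ang = orientation_angle(q1, q2)
            assert ang == pytest.approx(orientation_angle(q2, q1), abs=1e-9)
            assert ang == pytest.approx(orientation_angle(q1, -q2), abs=1e-9)
            r1 = Rotation.from_quat(np.roll(q1, -1)).as_matrix()
            r2 = Rotation.from_quat(np.roll(q2, -1)).as_matrix()
            tr = np.trace(r1.T @ r2)
            expect = math.degrees(math.acos(np.clip((tr - 1) / 2, -1, 1)))
            assert ang == pytest.approx(expect, abs=1e-6)
            assert 0.0 <= ang <= 180.0


class TestDetectLift:
    def test_ramp_crossing_index(self, cfg):
        n = int(2.0 * FS)
        elev = np.full(n, 100.0)
        rise = np.arange(n - 300) * (100.0 / (n - 300))
        elev[300:] += rise  # linear rise from 100 to 200 after 1 s
        rate = central_rate(elev, FS)
        idx = detect_lift(elev, rate, cfg, FS)
        # first sample strictly above baseline + 10 mm on the rise
        expect = 300 + int(np.ceil(10.0 / (100.0 / (n - 300)))) + 1
        assert abs(idx - expect) <= 1
        assert elev[idx] > 110.0 and elev[idx - 1] <= 110.0 + 1e-6

    def test_flat_trace_none(self, cfg):
        elev = np.full(600, 60.0)
        assert detect_lift(elev, np.zeros(600), cfg, FS) is None

    def test_subthreshold_noise_none(self, cfg):
        rng = np.random.default_rng(0)
        elev = 60.0 + np.clip(rng.normal(0, 1.0, 600), -3, 3)
        rate = central_rate(elev, FS)
        assert detect_lift(elev, rate, cfg, FS) is None

    def test_trial_shorter_than_baseline_window(self, cfg):
        with pytest.raises(ValueError):
            detect_lift(np.zeros(50), np.zeros(50), cfg, FS)


@pytest.fixture(scope="module")
def static_features():
    from epannot import idle_scenario

    rec, _ = render_scenario(idle_scenario(duration=2.0))
    return extract_features(rec, StimulusGeometry(), ThresholdConfig())


class TestExtractFeatures:
    def test_static_scene_speeds_zero_hull_constant(self, static_features):
        feat = static_features
        for s, v in feat.rel_speed.items():
            assert np.abs(v).max() < 1e-6
        for h, hv in feat.hull_size.items():
            assert np.ptp(hv) < 1e-3
        assert feat.lift_index is None
        assert feat.hull_at_lift == {"left": None, "right": None}

    def test_channel_lengths_match_recording(self, static_features):
        feat = static_features
        n = feat.n_samples
        for d in (feat.rel_speed, feat.hull_size, feat.hull_rate, feat.surf_dist,
                  feat.midpoint_inside, feat.finger_angle, feat.finger_angle_rate):
            for v in d.values():
                assert len(v) == n
        assert len(feat.elevation) == n == len(feat.elevation_rate)
        assert len(feat.to_dataframe()) == n

    def test_lm_scenario_exceeds_v_high(self, cfg, geom):
        rec, truth = render_scenario(ep_scenario("LM", seed=2))
        feat = extract_features(rec, geom, cfg)
        iv = truth.intervals[0]
        sel = (feat.t >= iv.t_start) & (feat.t < iv.t_end)
        v = feat.rel_speed["R_index_nail"][sel]
        assert v.max() > cfg.v_high_ms

    def test_rigid_transform_invariance_except_elevation(self, cfg, geom):
        """A shared rotation about z + translation in x,y leaves every
        feature unchanged (elevation is translation-sensitive by design,
        but a z-rotation + horizontal shift preserves it too)."""
        import copy

        rec, _ = render_scenario(ep_scenario("EN", seed=4), fs=300.0)
        # trim for speed
        for s in rec.pos:
            rec.pos[s] = rec.pos[s][900:1500]
            rec.quat[s] = rec.quat[s][900:1500]
        rec.t = rec.t[:600]
        feat0 = extract_features(rec, geom, cfg)

        rng = np.random.default_rng(21)
        ang = rng.uniform(0, 2 * np.pi)
        rot = Rotation.from_euler("z", ang)
        q_rot = np.roll(rot.as_quat(), 1)
        shift = np.array([rng.uniform(-300, 300), rng.uniform(-300, 300), 0.0])
        rec2 = copy.deepcopy(rec)
        for s in rec2.pos:
            rec2.pos[s] = rot.apply(rec2.pos[s]) + shift
            q = rec2.quat[s]
            rec2.quat[s] = np.array(
                [_quat_mul(q_rot, qk) for qk in q]
            )
        feat1 = extract_features(rec2, geom, cfg)

        for s in feat0.rel_speed:
            np.testing.assert_allclose(feat1.rel_speed[s], feat0.rel_speed[s], atol=1e-6)
            np.testing.assert_allclose(feat1.surf_dist[s], feat0.surf_dist[s], atol=1e-6)
        for h in ("left", "right"):
            np.testing.assert_allclose(feat1.hull_size[h], feat0.hull_size[h], rtol=1e-9)
            np.testing.assert_array_equal(feat1.midpoint_inside[h], feat0.midpoint_inside[h])
            np.testing.assert_allclose(feat1.finger_angle[h], feat0.finger_angle[h], atol=1e-6)
        np.testing.assert_allclose(feat1.elevation, feat0.elevation, atol=1e-6)


def _quat_mul(a, b):
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )
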