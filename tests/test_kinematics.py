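"""Sagittal angle conventions, invariances, and the tolerance band."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gaitwarp import (
    GaitConfig, angle_series, ankle_angle, generate_waveforms, hip_angle,
    knee_angle, project_markers, project_skeleton, tolerance_band,
)
from gaitwarp.kinematics import AngleSeries, infer_walking_direction


def rot(p, deg):
    a = np.radians(deg)
    c, s = np.cos(a), np.sin(a)
    p = np.asarray(p, float)
    return np.array([c * p[0] - s * p[1], s * p[0] + c * p[1]])


finite_coord = st.floats(-1000, 1000)


class TestHipAngle:
    def test_vertical_thigh_is_zero(self):
        assert hip_angle([0, 1], [0, 0]) == pytest.approx(0.0)

    def test_anterior_displacement_positive(self):
        # knee 45 deg anterior of vertical (walking toward +x)
        assert hip_angle([0, 0], [1, -1], direction=1) == pytest.approx(45.0)

    def test_posterior_displacement_negative(self):
        knee = [np.sin(np.radians(-10)), -np.cos(np.radians(-10))]
        assert hip_angle([0, 0], knee, direction=1) == pytest.approx(-10.0)

    def test_direction_flip_negates(self):
        assert hip_angle([0, 0], [1, -1], direction=-1) == pytest.approx(-45.0)

    def test_coincident_points_are_missing(self):
        assert np.isnan(hip_angle([1, 2], [1, 2]))


class TestKneeAngle:
    def test_collinear_is_zero(self):
        assert knee_angle([0, 2], [0, 1], [0, 0]) == pytest.approx(0.0)

    def test_interior_120_gives_60_flexion(self):
        # thigh down the y-axis; shank at 120 deg interior angle
        hip, knee = [0, 1], [0, 0]
        ankle = knee + rot([0, 1], 120)  # 120 deg from the upward thigh line
        assert knee_angle(hip, knee, ankle) == pytest.approx(60.0)

    def test_right_angle_at_knee(self):
        assert knee_angle([0, 1], [0, 0], [1, 0]) == pytest.approx(90.0)

    def test_symmetric_in_hip_and_ankle(self, rng):
        for _ in range(20):
            h, k, a = rng.normal(size=(3, 2))
            assert knee_angle(h, k, a) == pytest.approx(knee_angle(a, k, h))

    def test_coincident_points_are_missing(self):
        assert np.isnan(knee_angle([0, 1], [0, 1], [1, 0]))


class TestAnkleAngle:
    def test_perpendicular_foot_is_zero(self):
        assert ankle_angle([0, 1], [0, 0], [1, 0]) == pytest.approx(0.0)

    def test_80_degree_interior_is_dorsiflexion(self):
        toe = rot([0, 1], -80)  # 80 deg from the heel->knee line
        assert ankle_angle([0, 1], [0, 0], toe) == pytest.approx(10.0)

    def test_110_degree_interior_is_plantarflexion(self):
        toe = rot([0, 1], -110)
        assert ankle_angle([0, 1], [0, 0], toe) == pytest.approx(-20.0)

    def test_coincident_points_are_missing(self):
        assert np.isnan(ankle_angle([0, 1], [0, 0], [0, 0]))


class TestInvariances:
    @given(
        pts=st.lists(st.tuples(finite_coord, finite_coord), min_size=3, max_size=3),
        tx=st.floats(-50, 50), ty=st.floats(-50, 50),
        scale=st.floats(0.1, 10.0),
    )
    def test_translation_and_scale_invariance(self, pts, tx, ty, scale):
        h, k, a = (np.array(p) for p in pts)
        shift = np.array([tx, ty])

        def xform(p):
            return scale * p + shift

        for fn, args in ((hip_angle, (h, k)),
                         (knee_angle, (h, k, a)),
                         (ankle_angle, (h, k, a))):
            before = fn(*args)
            after = fn(*(xform(p) for p in args))
            if np.isnan(before):
                assert np.isnan(after)
            else:
                assert after == pytest.approx(before, abs=1e-6)

    @given(
        pts=st.lists(st.tuples(finite_coord, finite_coord), min_size=3, max_size=3),
        angle=st.floats(-179, 179),
    )
    def test_rotation_moves_hip_but_not_knee_or_ankle(self, pts, angle):
        h, k, a = (np.array(p) for p in pts)
        hr, kr, ar = (rot(p, angle) for p in (h, k, a))
        knee_before, knee_after = knee_angle(h, k, a), knee_angle(hr, kr, ar)
        ank_before, ank_after = ankle_angle(h, k, a), ankle_angle(hr, kr, ar)
        for before, after in ((knee_before, knee_after), (ank_before, ank_after)):
            if np.isnan(before):
                assert np.isnan(after)
            else:
                assert after == pytest.approx(before, abs=1e-6)
        hip_before, hip_after = hip_angle(h, k), hip_angle(hr, kr)
        if not np.isnan(hip_before):
            delta = (hip_after - hip_before - angle + 180) % 360 - 180
            assert delta == pytest.approx(0.0, abs=1e-6)


class TestAngleSeriesComputation:
    def test_recovers_generator_truth(self, default_truth, default_skeleton):
        for joint in ("hip", "knee", "ankle"):
            rec = angle_series(default_skeleton, joint, "left")
            truth = default_truth.angle(joint, "left")
            assert np.nanmax(np.abs(rec.values - truth.values)) < 0.5

    def test_marker_input_matches_keypoint_input(self, default_truth, default_skeleton):
        markers = project_markers(default_truth)
        for joint in ("hip", "knee", "ankle"):
            from_markers = angle_series(markers, joint, "right")
            from_kp = angle_series(default_skeleton, joint, "right")
            assert np.nanmax(np.abs(from_markers.values - from_kp.values)) < 1e-6

    def test_missingness_propagates_per_frame(self, default_skeleton):
        kp = default_skeleton.copy()
        kp.missing[5, kp.index("LKnee")] = True
        out = angle_series(kp, "knee", "left")
        assert out.mask[5]
        assert not out.mask[6]
        assert np.count_nonzero(out.mask) == 1

    def test_translation_and_scaling_leave_series_unchanged(self, default_skeleton):
        kp = default_skeleton.copy()
        kp.x = kp.x * 2.0 + 111.0
        kp.y = kp.y * 2.0 + 57.0
        for joint in ("knee", "ankle", "hip"):
            a = angle_series(default_skeleton, joint, "left").values
            b = angle_series(kp, joint, "left").values
            assert np.nanmax(np.abs(a - b)) < 1e-9

    def test_mirrored_skeleton_gives_identical_series(self, default_truth):
        mirrored = project_skeleton(default_truth)
        mirrored.x = -mirrored.x  # walk toward -x; direction is re-inferred
        for joint in ("hip", "knee", "ankle"):
            a = angle_series(project_skeleton(default_truth), joint, "left").values
            b = angle_series(mirrored, joint, "left").values
            assert np.nanmax(np.abs(a - b)) < 1e-9

    def test_required_marker_absent_is_descriptive_error(self, default_truth):
        markers = project_markers(default_truth)
        names = list(markers.marker_names)
        j = names.index("LKNE")
        kept = [n for i, n in enumerate(names) if i != j]
        import gaitwarp.pose_io as pio

        reduced = pio.MarkerSeries(
            data=np.delete(markers.data, j, axis=1),
            missing=np.delete(markers.missing, j, axis=1),
            marker_names=tuple(kept), fs=markers.fs,
        )
        with pytest.raises(KeyError, match="LKNE"):
            angle_series(reduced, "knee", "left")

    def test_walking_direction_inference(self):
        assert infer_walking_direction(np.array([0.0, 1.0, 2.0])) == 1.0
        assert infer_walking_direction(np.array([2.0, 1.0, 0.0])) == -1.0


class TestToleranceBand:
    @staticmethod
    def _series(joint="knee", values=(10.0, 20.0, 30.0)):
        return AngleSeries(joint=joint, side="left", values=np.array(values))

    def test_knee_band_half_width(self):
        band = tolerance_band(self._series(), fraction=0.30,
                              rom_table={"knee": 140.0})
        assert band.half_width == pytest.approx(42.0)

    def test_full_fraction_is_full_rom(self):
        band = tolerance_band(self._series(), fraction=1.0,
                              rom_table={"knee": 140.0})
        assert band.half_width == pytest.approx(140.0)

    def test_identical_series_fully_inside(self):
        s = self._series()
        band = tolerance_band(s)
        assert band.coverage(s) == 100.0

    def test_unknown_joint_rejected(self):
        with pytest.raises(KeyError):
            tolerance_band(self._series(joint="elbow"))
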