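import numpy as np
import pytest

from engagetrack.detection import FrameRecord
from engagetrack.metrics import DISTRACTED, ENGAGED
from engagetrack.scoring import (ACTIVE, INTER_TRIAL, CameraConfigError,
                                 TrialWindow, annotation_state,
                                 classify_frame, classify_record,
                                 score_session, score_trial)

E, D = ENGAGED, DISTRACTED


def rec(ts, obs=(), cam="fused", idx=0):
    return FrameRecord(camera_id=cam, frame_index=idx, timestamp=ts,
                       observations=tuple(obs))


class TestClassifyFrame:
    def test_in_roi_facing_wall_is_engaged(self, simple_classifier,
                                           unit_square_obs):
        # center (75, 50), front edge 1 -> heading (1, 0) -> yaw 90
        obs = unit_square_obs(dx=70, dy=45)
        assert classify_frame(obs, simple_classifier) == E

    def test_grazing_yaw_is_distracted(self, simple_classifier,
                                       unit_square_obs):
        # heading (0,1) is parallel to the wall: yaw 0, below the 5 deg gate
        obs = unit_square_obs(dx=70, dy=45)
        cfg = simple_classifier
        assert classify_frame(obs, cfg) == E
        import dataclasses
        cfg2 = dataclasses.replace(cfg, front_edge=2)  # heading (0, 1): yaw 0
        assert classify_frame(obs, cfg2) == D

    def test_occlusion_is_distracted(self, simple_classifier):
        assert classify_frame(None, simple_classifier) == D

    def test_outside_roi_is_distracted(self, simple_classifier,
                                       unit_square_obs):
        # correct yaw but center (15, 50) left of the ROI
        obs = unit_square_obs(dx=10, dy=45)
        assert classify_frame(obs, simple_classifier) == D

    def test_unconfigured_camera_raises(self, simple_classifier,
                                        unit_square_obs):
        obs = unit_square_obs(dx=70, dy=45, camera_id="cam9")
        with pytest.raises(CameraConfigError):
            classify_frame(obs, simple_classifier)

    def test_yaw_window_endpoints_inclusive(self, simple_classifier,
                                            unit_square_obs):
        import dataclasses

        from engagetrack.geometry import MarkerObservation, Point2D

        # rotate the square so yaw is exactly 5 deg (heading barely toward wall)
        import math
        theta = math.radians(90.0 - 5.0)  # rotate heading (1,0) toward (0,1)
        R = np.array([[math.cos(theta), -math.sin(theta)],
                      [math.sin(theta), math.cos(theta)]])
        base = np.array([[70, 45], [80, 45], [80, 55], [70, 55]], float)
        c = base.mean(axis=0)
        pts = (base - c) @ R.T + c
        obs = MarkerObservation(
            camera_id="cam1", frame_index=0, timestamp=0.0, marker_id=0,
            corners=tuple(Point2D(*p) for p in pts))
        assert classify_frame(obs, simple_classifier) == E


class TestAnnotationState:
    @pytest.mark.parametrize("kind,label,color", [
        (ACTIVE, E, "green"), (ACTIVE, D, "yellow"),
        (INTER_TRIAL, E, "purple"), (INTER_TRIAL, D, "pink")])
    def test_color_mapping(self, kind, label, color):
        assert annotation_state(kind, label) == color

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            annotation_state("active", "asleep")


class TestScoreTrial:
    def _frames(self, labels, simple_classifier, unit_square_obs):
        """Frame records whose classification matches the given labels."""
        out = []
        for i, lab in enumerate(labels):
            if lab == E:
                obs = (unit_square_obs(dx=70, dy=45, timestamp=float(i)),)
            elif lab == D:
                obs = (unit_square_obs(dx=10, dy=45, timestamp=float(i)),)
            else:  # no detection
                obs = ()
            out.append(rec(float(i), obs))
        return out

    def test_any_frame_rule(self, simple_classifier, unit_square_obs):
        frames = self._frames([D, D, E, D], simple_classifier,
                              unit_square_obs)
        w = TrialWindow(0, ACTIVE, 0.0, 6.0)
        s = score_trial(frames, w, simple_classifier)
        assert s.label == E
        assert s.n_frames_engaged == 1
        assert s.first_engaged_timestamp == 2.0

    def test_all_distracted(self, simple_classifier, unit_square_obs):
        frames = self._frames([D, D, D], simple_classifier, unit_square_obs)
        s = score_trial(frames, TrialWindow(0, ACTIVE, 0.0, 6.0),
                        simple_classifier)
        assert s.label == D and s.n_frames_engaged == 0

    def test_empty_frame_set_defaults_distracted(self, simple_classifier):
        s = score_trial([], TrialWindow(0, ACTIVE, 0.0, 6.0),
                        simple_classifier)
        assert s.label == D and s.n_frames_seen == 0

    def test_monotone_in_engaged_frames(self, simple_classifier,
                                        unit_square_obs):
        # adding an engaged frame never flips engaged -> distracted
        frames = self._frames([D, E, D], simple_classifier, unit_square_obs)
        w = TrialWindow(0, ACTIVE, 0.0, 6.0)
        assert score_trial(frames, w, simple_classifier).label == E
        more = frames + self._frames([E], simple_classifier, unit_square_obs)
        assert score_trial(more, w, simple_classifier).label == E
        # removing frames never flips distracted -> engaged
        dis = self._frames([D, D], simple_classifier, unit_square_obs)
        assert score_trial(dis, w, simple_classifier).label == D
        assert score_trial(dis[:1], w, simple_classifier).label == D

    def test_zero_length_window_rejected(self):
        with pytest.raises(ValueError):
            TrialWindow(0, ACTIVE, 5.0, 5.0)


class TestScoreSession:
    def _windows(self, n):
        out = []
        for i in range(n):
            t = 9.0 * i
            out.append(TrialWindow(i, ACTIVE, t, t + 6.0))
            out.append(TrialWindow(i, INTER_TRIAL, t + 6.0, t + 9.0))
        return out

    def test_engaged_only_in_second_trial(self, simple_classifier,
                                          unit_square_obs):
        windows = self._windows(3)
        frames = [rec(1.0, (unit_square_obs(dx=10, dy=45, timestamp=1.0),)),
                  rec(10.0, (unit_square_obs(dx=70, dy=45, timestamp=10.0),)),
                  rec(19.0, ())]
        scores = score_session(frames, windows, simple_classifier)
        assert [s.label for s in scores] == [D, E, D]

    def test_no_frames_all_distracted(self, simple_classifier):
        scores = score_session([], self._windows(4), simple_classifier)
        assert [s.label for s in scores] == [D] * 4

    def test_intertrial_frames_never_scored(self, simple_classifier,
                                            unit_square_obs):
        # an engaged pose during the inter-trial period must not score
        windows = self._windows(1)
        frames = [rec(7.0, (unit_square_obs(dx=70, dy=45, timestamp=7.0),))]
        scores = score_session(frames, windows, simple_classifier)
        assert [s.label for s in scores] == [D]

    def test_union_equals_or_of_per_camera_labels(self, right_wall,
                                                  unit_square_obs):
        from engagetrack.geometry import Point2D, RegionOfInterest
        from engagetrack.scoring import ClassifierConfig

        roi = {c: (RegionOfInterest(camera_id=c, vertices=(
            Point2D(40, 0), Point2D(100, 0), Point2D(100, 100),
            Point2D(40, 100))),) for c in ("cam1", "cam2")}
        cfg = ClassifierConfig(rois=roi,
                               walls={"cam1": right_wall, "cam2": right_wall},
                               front_edge=1)
        windows = self._windows(2)
        rng = np.random.default_rng(5)
        f1, f2, fu = [], [], []
        for i in range(12):
            t = 1.5 * i
            o1 = (unit_square_obs(dx=70 if rng.random() < 0.4 else 10,
                                  dy=45, camera_id="cam1", timestamp=t),)
            o2 = (unit_square_obs(dx=70 if rng.random() < 0.4 else 10,
                                  dy=45, camera_id="cam2", timestamp=t),)
            f1.append(rec(t, o1, cam="cam1"))
            f2.append(rec(t, o2, cam="cam2"))
            fu.append(rec(t, o1 + o2))
        s1 = score_session(f1, windows, cfg)
        s2 = score_session(f2, windows, cfg)
        su = score_session(fu, windows, cfg)
        for a, b, u in zip(s1, s2, su):
            assert (u.label == E) == ((a.label == E) or (b.label == E))

    def test_overlapping_windows_rejected(self, simple_classifier):
        ws = [TrialWindow(0, ACTIVE, 0.0, 6.0),
              TrialWindow(1, ACTIVE, 5.0, 11.0)]
        with pytest.raises(ValueError):
            score_session([], ws, simple_classifier)


class TestClassifyRecord:
    def test_wrong_marker_id_ignored(self, simple_classifier,
                                     unit_square_obs):
        obs = unit_square_obs(dx=70, dy=45, marker_id=3)
        assert classify_record(rec(0.0, (obs,)), simple_classifier) == D
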