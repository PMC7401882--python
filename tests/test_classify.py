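"""Decision tree, smoothing, priority resolution and lying detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from actitree import (
    ADULT,
    CHILD,
    DeviceOrientation,
    LabelSeries,
    SmoothingConfig,
    ThresholdSet,
    classify_frame,
    classify_frames,
    classify_recording,
    compute_features,
    detect_lying,
    gen_static,
    resolve_multilabel,
    smooth_labels,
    to_device_frame,
)
from actitree.boundary import node_boundaries
from actitree.classify import read_labels, write_labels
from actitree.errors import AlignmentError, ConfigurationError, ValidationError
from actitree.features import FeatureFrame


def frame(sd_long=0.0, sd_ap=0.0, sd_lat=0.0, inc=0.0, theta=0.0):
    return FeatureFrame(
        t=0.0, sd_long=sd_long, sd_ap=sd_ap, sd_lat=sd_lat,
        sd_max=max(sd_long, sd_ap, sd_lat), inc_deg=inc, theta_deg=theta,
        mean_vec=(1.0, 0.0, 0.0),
    )


def oracle_tree(sd_long, sd_max, inc, theta, th):
    """Independent rule-by-rule restatement of the five tree conditions."""
    dynamic = sd_long > th.sd_move
    if dynamic and theta > th.theta_bike:
        return "bike"
    if dynamic and sd_long > th.sd_run:
        return "run"
    if dynamic:
        return "walk"
    if inc > th.inc_sit:
        return "sit"
    if sd_max > th.sd_still:
        return "move"
    return "stand"


class TestDecisionTree:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(sd_long=0.02, inc=90.0, sd_lat=0.03), "sit"),
            (dict(sd_long=0.3, theta=40.0), "bike"),
            (dict(sd_long=0.3, theta=10.0), "walk"),
            (dict(sd_long=0.8, theta=0.0), "run"),
            (dict(sd_long=0.5, theta=0.0), "walk"),
            (dict(sd_long=0.05, inc=10.0, sd_lat=0.2), "move"),
            (dict(sd_long=0.05, inc=10.0, sd_lat=0.05), "stand"),
        ],
    )
    def test_child_preset_examples(self, kwargs, expected):
        assert classify_frame(frame(**kwargs), CHILD) == expected

    def test_exhaustive_grid_matches_independent_oracle(self):
        sds = [0.0, 0.05, 0.09, 0.1, 0.11, 0.3, 0.64, 0.65, 0.66, 1.2]
        maxes = [0.0, 0.12, 0.13, 0.14, 0.3]
        incs = [0.0, 47.0, 47.5, 48.0, 90.0]
        thetas = [-10.0, 0.0, 22.0, 22.5, 23.0, 60.0]
        for th in (CHILD, ADULT):
            for sd, mx, inc, theta in itertools.product(sds, maxes, incs, thetas):
                f = frame(sd_long=sd, sd_lat=max(mx, sd), inc=inc, theta=theta)
                assert classify_frame(f, th) == oracle_tree(
                    f.sd_long, f.sd_max, inc, theta, th
                )

    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            # equality takes the false branch at every node
            (dict(sd_long=0.1, inc=10.0), "stand"),
            (dict(sd_long=0.2, theta=22.5), "walk"),
            (dict(sd_long=0.65, theta=0.0), "walk"),
            (dict(sd_long=0.02, inc=47.5), "stand"),
            (dict(sd_long=0.02, sd_lat=0.13, inc=10.0), "stand"),
        ],
    )
    def test_equality_takes_false_branch(self, kwargs, expected):
        assert classify_frame(frame(**kwargs), CHILD) == expected

    def test_bisection_recovers_configured_thresholds(self):
        custom = ThresholdSet(
            sd_move=0.17, theta_bike=31.0, sd_run=0.81, inc_sit=55.0,
            sd_still=0.21, back_lie=70.0,
        )
        found = node_boundaries(custom, tol=1e-9)
        for name in ("sd_move", "theta_bike", "sd_run", "inc_sit", "sd_still"):
            assert found[name] == pytest.approx(getattr(custom, name), abs=1e-6)
        assert found["back_lie"] == pytest.approx(70.0, abs=1e-6)

    def test_presets_differ_only_in_four_calibrated_nodes(self):
        assert CHILD.sd_move == ADULT.sd_move == 0.1
        assert CHILD.back_lie == ADULT.back_lie
        diffs = {
            name
            for name in ("sd_move", "theta_bike", "sd_run", "inc_sit", "sd_still", "back_lie")
            if getattr(CHILD, name) != getattr(ADULT, name)
        }
        assert diffs == {"theta_bike", "sd_run", "inc_sit", "sd_still"}

    def test_invalid_threshold_ordering_rejected(self):
        with pytest.raises(ValidationError):
            ThresholdSet(sd_move=0.7, theta_bike=22.5, sd_run=0.65,
                         inc_sit=47.5, sd_still=0.13, back_lie=65.0)


class TestSmoothing:
    def test_majority_removes_single_outlier(self):
        s = LabelSeries(("walk", "walk", "run", "walk", "walk"))
        out = smooth_labels(s, SmoothingConfig(mode="majority", window_s=5))
        assert out.labels == ("walk",) * 5

    @pytest.mark.parametrize("mode", ["per_activity_median", "majority", "none"])
    def test_constant_series_unchanged(self, mode):
        s = LabelSeries(("sit",) * 9)
        out = smooth_labels(s, SmoothingConfig(mode=mode, window_s=5))
        assert out.labels == s.labels

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            SmoothingConfig(mode="majority", window_s=4)

    def test_per_activity_median_matches_binary_oracle(self):
        labels = ("walk", "walk", "sit", "walk", "run", "run", "walk", "run", "run")
        s = LabelSeries(labels)
        _, assigned = smooth_labels(
            s, SmoothingConfig(mode="per_activity_median", window_s=3),
            return_assignments=True,
        )
        n = len(labels)
        for label in set(labels):
            ind = [1 if l == label else 0 for l in labels]
            for i in range(n):
                lo, hi = max(0, i - 1), min(n, i + 2)
                window = ind[lo:hi]
                majority = sum(window) * 2 > len(window)  # binary median
                assert (label in assigned[i]) == majority

    @given(
        st.lists(st.sampled_from(["sit", "stand", "walk", "run", "bike"]),
                 min_size=1, max_size=40),
        st.sampled_from([("per_activity_median", 3), ("per_activity_median", 5),
                         ("majority", 3), ("majority", 5)]),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_smoothing_never_invents_labels(self, labels, mode_win):
        mode, win = mode_win
        s = LabelSeries(tuple(labels))
        out = smooth_labels(s, SmoothingConfig(mode=mode, window_s=win))
        half = win // 2
        n = len(labels)
        for i, label in enumerate(out.labels):
            window = set(labels[max(0, i - half):min(n, i + half + 1)])
            assert label in window | {"undefined"}


class TestPriorityResolution:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            ({"sit", "walk"}, "sit"),
            ({"bike", "run"}, "bike"),
            ({"walk", "stand"}, "walk"),
            ({"run", "move"}, "run"),
            ({"lie", "bike", "run"}, "lie"),
            (set(), "undefined"),
        ],
    )
    def test_priority_rules(self, labels, expected):
        out = resolve_multilabel([labels])
        assert out.labels == (expected,)

    def test_walk_run_tie_goes_to_walk(self):
        out = resolve_multilabel([{"walk", "run"}])
        assert out.labels == ("walk",)

    def test_walk_run_resolved_by_support(self):
        support = {"walk": np.array([0.2]), "run": np.array([0.8])}
        out = resolve_multilabel([{"walk", "run"}], support=support)
        assert out.labels == ("run",)

    def test_resolution_is_set_order_independent(self, rng):
        pool = ["sit", "stand", "move", "walk", "run", "bike", "lie"]
        for _ in range(50):
            members = rng.choice(pool, size=rng.integers(1, 5), replace=False)
            a = resolve_multilabel([set(members)])
            b = resolve_multilabel([set(reversed(list(members)))])
            assert a.labels == b.labels


class TestLyingDetection:
    def _trunk_frame(self, inc):
        return FeatureFrame(t=0.0, sd_long=0.0, sd_ap=0.0, sd_lat=0.0, sd_max=0.0,
                            inc_deg=inc, theta_deg=0.0, mean_vec=(1, 0, 0))

    @pytest.mark.parametrize(
        "label,trunk_inc,expected",
        [
            ("sit", 80.0, "lie"),
            ("stand", 80.0, "stand"),
            ("sit", 65.0, "sit"),  # strict > at the boundary
            ("sit", 30.0, "sit"),
        ],
    )
    def test_lying_rule(self, label, trunk_inc, expected):
        out = detect_lying(LabelSeries((label,)), [self._trunk_frame(trunk_inc)], CHILD)
        assert out.labels == (expected,)

    def test_length_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            detect_lying(LabelSeries(("sit", "sit")), [self._trunk_frame(80.0)], CHILD)


class TestClassifyRecording:
    def test_synthetic_sitting_is_all_sit(self):
        rec = gen_static(85.0, 0.02, 30.0, fs=100.0, seed=4)
        series = classify_recording(rec)
        assert set(series.labels) == {"sit"}

    def test_deterministic(self):
        rec = gen_static(85.0, 0.02, 20.0, fs=100.0, seed=4)
        assert classify_recording(rec).labels == classify_recording(rec).labels

    @pytest.mark.parametrize("preset", ["preschool", "school"])
    def test_orientation_invariance(self, preset):
        canon = gen_static(30.0, 0.05, 20.0, fs=100.0, seed=8)
        device = to_device_frame(canon, DeviceOrientation(preset))
        a = classify_recording(canon)
        b = classify_recording(device, orientation=DeviceOrientation(preset))
        assert a.labels == b.labels

    def test_no_smoothing_equals_frame_by_frame(self):
        rec = gen_static(85.0, 0.02, 20.0, fs=30.0, seed=4)
        series = classify_recording(rec, cfg=SmoothingConfig(mode="none"))
        frames = compute_features(rec)
        assert series.labels == classify_frames(frames, CHILD).labels

    def test_single_sensor_never_emits_lie(self):
        rec = gen_static(120.0, 0.02, 30.0, fs=30.0, seed=4)  # reclined thigh
        series = classify_recording(rec)
        assert "lie" not in series.labels

    def test_below_working_rate_rejected(self):
        rec = gen_static(10.0, 0.02, 20.0, fs=20.0, seed=1)
        with pytest.raises(ValidationError):
            classify_recording(rec)


def test_label_csv_round_trip(tmp_path):
    series = LabelSeries(("sit", "walk", "run"), t0=0.0)
    p = tmp_path / "labels.csv"
    write_labels(p, series)
    assert read_labels(p) == series
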