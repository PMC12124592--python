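"""Frame conversion, movement segmentation, time normalization and AUC."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mousetrace import (
    NormalizedPath,
    ScreenGeometry,
    compute_auc,
    measure_trial,
    mirror_to_right,
    segment_movement,
    time_normalize,
    to_analysis_frame,
)
from mousetrace.geometry import GeometryError
from mousetrace.preprocess import AnalysisPath

from conftest import make_trial, straight_reach


def chord_frame_auc(points: np.ndarray) -> float:
    """Independent oracle: rotate into chord coordinates and integrate.

    With u along the chord and v the leftward normal, the signed area
    between the polyline and the chord is the trapezoid integral of v du.
    """
    p = np.asarray(points, dtype=float)
    chord = p[-1] - p[0]
    L = np.hypot(*chord)
    d = chord / L
    n = np.array([-d[1], d[0]])
    u = (p - p[0]) @ d
    v = (p - p[0]) @ n
    return float(np.sum((u[1:] - u[:-1]) * (v[1:] + v[:-1]) / 2.0))


def dense_polyline(vertices: np.ndarray, per_segment: int = 50) -> np.ndarray:
    """Resample a polyline keeping every vertex (preserves its shape exactly)."""
    vertices = np.asarray(vertices, dtype=float)
    pts = [vertices[:1]]
    for a, b in zip(vertices[:-1], vertices[1:]):
        frac = np.linspace(0.0, 1.0, per_segment + 1)[1:, None]
        pts.append(a + frac * (b - a))
    return np.vstack(pts)


class TestAnalysisFrame:
    @pytest.mark.parametrize(
        "raw_point, expected",
        [
            ("home", (0.0, 0.0)),
            ("target", (100.0, 200.0)),
            ("midway", (50.0, 100.0)),
        ],
    )
    def test_landmarks_map_to_xu(self, geom, raw_point, expected):
        hx, hy = geom.home_center
        tx, ty = geom.right_target_center
        coords = {
            "home": (hx, hy),
            "target": (tx, ty),
            "midway": ((hx + tx) / 2.0, (hy + ty) / 2.0),
        }[raw_point]
        trial = make_trial([(0.0, *coords)])
        path = to_analysis_frame(trial, geom)
        np.testing.assert_allclose(path.points[0], expected, atol=1e-12)

    def test_left_target_center_maps_to_minus_100(self, geom):
        trial = make_trial([(0.0, *geom.left_target_center)], clicked_side="left",
                           chosen="contemporary")
        path = to_analysis_frame(trial, geom)
        np.testing.assert_allclose(path.points[0], (-100.0, 200.0), atol=1e-12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(GeometryError):
            ScreenGeometry(
                home_center=(400.0, 570.0),
                left_target_center=(400.0, 100.0),
                right_target_center=(400.0, 100.0),
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 10.0))
    def test_display_scale_invariance(self, geom, scale):
        """Scaling raw pixels and display_scale together changes nothing."""
        base = straight_reach(geom, scale=1.0)
        scaled = straight_reach(geom, scale=scale)
        m0, p0 = measure_trial(base, geom)
        m1, p1 = measure_trial(scaled, geom)
        assert m0.it_ms == pytest.approx(m1.it_ms)
        assert m0.mt_ms == pytest.approx(m1.mt_ms)
        assert m0.auc_xu2 == pytest.approx(m1.auc_xu2, abs=1e-9)
        np.testing.assert_allclose(p0.points, p1.points, atol=1e-9)


class TestMirror:
    def test_left_path_endpoint_mirrored(self, geom):
        path = AnalysisPath(times=np.array([0.0]), points=np.array([[-100.0, 200.0]]))
        out = mirror_to_right(path, "left")
        np.testing.assert_allclose(out.points[0], (100.0, 200.0))
        assert out.mirrored

    def test_right_path_unchanged(self, geom):
        path = AnalysisPath(times=np.array([0.0]), points=np.array([[3.0, 4.0]]))
        out = mirror_to_right(path, "right")
        assert out is path

    def test_mirror_twice_is_identity(self):
        pts = np.array([[1.0, 2.0], [-3.0, 4.0]])
        path = AnalysisPath(times=np.array([0.0, 1.0]), points=pts.copy())
        twice = mirror_to_right(mirror_to_right(path, "left"), "left")
        np.testing.assert_allclose(twice.points, pts)
        assert not twice.mirrored


class TestSegmentation:
    def test_exit_and_entry_on_a_clean_reach(self, geom):
        trial = straight_reach(geom, it_ms=400.0, mt_ms=800.0, n=201)
        it, mt, window, reason = segment_movement(trial, geom)
        assert reason == "none"
        # exit: first sample strictly outside the 60x60 home box
        xy = trial.samples[:, 1:3]
        hx, hy = geom.home_center
        outside = (np.abs(xy[:, 0] - hx) > 30) | (np.abs(xy[:, 1] - hy) > 30)
        assert window[0] == np.flatnonzero(outside)[0]
        tx, ty = geom.right_target_center
        inside = np.hypot(xy[:, 0] - tx, xy[:, 1] - ty) <= 20.0
        assert window[1] == np.flatnonzero(inside)[0]
        assert it == trial.samples[window[0], 0] - trial.onset_ms
        assert mt == trial.samples[window[1], 0] - trial.samples[window[0], 0]

    def test_all_samples_inside_home_is_no_target_entry(self, geom):
        hx, hy = geom.home_center
        trial = make_trial([(t, hx + 1.0, hy - 2.0) for t in range(0, 500, 20)])
        it, mt, window, reason = segment_movement(trial, geom)
        assert reason == "no_target_entry"
        assert np.isnan(it) and np.isnan(mt) and window is None

    def test_never_entering_circle_is_no_target_entry(self, geom):
        hx, hy = geom.home_center
        # leaves home, wanders, never approaches the target center
        trial = make_trial([(0, hx, hy), (50, hx + 200, hy), (100, hx + 250, hy)])
        *_, reason = segment_movement(trial, geom)
        assert reason == "no_target_entry"

    def test_exit_on_first_sample_after_onset(self, geom):
        tx, ty = geom.right_target_center
        hx, hy = geom.home_center
        trial = make_trial(
            [(120.0, hx + 100.0, hy - 100.0), (200.0, tx, ty)], onset_ms=100.0
        )
        it, mt, window, reason = segment_movement(trial, geom)
        assert it == 20.0 and mt == 80.0 and window == (0, 1)

    def test_onset_offsets_initiation_time(self, geom):
        a = straight_reach(geom, onset_ms=0.0)
        b = straight_reach(geom, onset_ms=2000.0)
        it_a, mt_a, *_ = segment_movement(a, geom)
        it_b, mt_b, *_ = segment_movement(b, geom)
        assert it_a == pytest.approx(it_b)
        assert mt_a == pytest.approx(mt_b)


class TestTimeNormalize:
    def test_two_sample_window_gives_collinear_grid(self):
        path = AnalysisPath(
            times=np.array([0.0, 1000.0]),
            points=np.array([[0.0, 0.0], [100.0, 200.0]]),
            movement_window=(0, 1),
        )
        npath = time_normalize(path)
        frac = np.linspace(0.0, 1.0, 101)
        np.testing.assert_allclose(npath.points[:101, 0], 100.0 * frac, atol=1e-9)
        np.testing.assert_allclose(npath.points[:101, 1], 200.0 * frac, atol=1e-9)
        np.testing.assert_allclose(npath.points[101], (100.0, 200.0))

    def test_samples_on_grid_times_reproduced_exactly(self):
        t = np.linspace(100.0, 600.0, 101)
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(101, 2))
        path = AnalysisPath(times=t, points=pts, movement_window=(0, 100))
        npath = time_normalize(path)
        np.testing.assert_allclose(npath.points[:101], pts, atol=1e-9)

    def test_bent_path_matches_brute_force_interpolation(self):
        t = np.array([0.0, 300.0, 1000.0])
        pts = np.array([[0.0, 0.0], [-10.0, 100.0], [100.0, 200.0]])
        path = AnalysisPath(times=t, points=pts, movement_window=(0, 2))
        npath = time_normalize(path)
        for k, g in enumerate(np.linspace(0.0, 1000.0, 101)):
            # brute force: locate bracketing samples and interpolate by hand
            j = int(np.searchsorted(t, g, side="right")) - 1
            j = min(j, len(t) - 2)
            w = (g - t[j]) / (t[j + 1] - t[j])
            expected = (1 - w) * pts[j] + w * pts[j + 1]
            np.testing.assert_allclose(npath.points[k], expected, atol=1e-9)

    def test_endpoints_are_window_samples_and_appended_final(self, geom):
        trial = straight_reach(geom)
        m, npath = measure_trial(trial, geom)
        apath = mirror_to_right(to_analysis_frame(trial, geom), trial.clicked_side)
        it, mt, window, _ = segment_movement(trial, geom)
        np.testing.assert_allclose(npath.points[0], apath.points[window[0]])
        np.testing.assert_allclose(npath.points[100], apath.points[window[1]])
        np.testing.assert_allclose(npath.points[101], apath.points[-1])

    def test_single_sample_window_rejected(self):
        path = AnalysisPath(
            times=np.array([0.0]), points=np.zeros((1, 2)), movement_window=(0, 0)
        )
        with pytest.raises(ValueError, match="2 samples"):
            time_normalize(path)


class TestAUC:
    def test_straight_path_is_zero(self):
        pts = dense_polyline([[0.0, 0.0], [100.0, 200.0]])
        assert compute_auc(pts) == pytest.approx(0.0, abs=1e-9)

    def test_bulge_toward_opposite_side_is_plus_6000(self):
        pts = dense_polyline([[0.0, 0.0], [-10.0, 100.0], [100.0, 200.0]])
        assert compute_auc(pts) == pytest.approx(6000.0, rel=1e-9)

    def test_bulge_away_from_opposite_side_is_minus_6000(self):
        pts = dense_polyline([[0.0, 0.0], [110.0, 100.0], [100.0, 200.0]])
        assert compute_auc(pts) == pytest.approx(-6000.0, rel=1e-9)

    def test_degenerate_chord_warns_and_returns_zero(self):
        loop = dense_polyline([[0.0, 0.0], [10.0, 10.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            assert compute_auc(loop) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_chord_frame_oracle_on_random_polylines(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(scale=10.0, size=(102, 2)), axis=0)
        pts[-1] += (50.0, 50.0)  # keep the chord non-degenerate
        expected = chord_frame_auc(pts)
        assert compute_auc(pts) == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_mirror_antisymmetry(self):
        rng = np.random.default_rng(3)
        pts = np.cumsum(rng.normal(scale=5.0, size=(102, 2)), axis=0)
        pts[-1] += (40.0, 80.0)
        mirrored = pts * np.array([-1.0, 1.0])
        assert compute_auc(mirrored) == pytest.approx(-compute_auc(pts), rel=1e-12)


class TestMeasureTrial:
    def test_left_and_right_mirror_trials_give_identical_measures(self, geom):
        right = straight_reach(geom, side="right", n=77)
        left = straight_reach(geom, side="left", n=77, chosen="contemporary")
        mr, pr = measure_trial(right, geom)
        ml, pl = measure_trial(left, geom)
        assert mr.it_ms == ml.it_ms and mr.mt_ms == ml.mt_ms
        assert mr.auc_xu2 == pytest.approx(ml.auc_xu2, abs=1e-9)
        np.testing.assert_allclose(pr.points, pl.points, atol=1e-9)

    @pytest.mark.parametrize(
        "comparison, intention, chosen, is_error",
        [
            ("past", "more_innovative", "contemporary", False),
            ("past", "more_innovative", "historic", True),
            ("past", "less_innovative", "historic", False),
            ("future", "less_innovative", "innovative", True),
            ("future", "more_innovative", "innovative", False),
        ],
    )
    def test_error_flag_follows_relative_innovativeness(
        self, geom, comparison, intention, chosen, is_error
    ):
        trial = straight_reach(
            geom, comparison_type=comparison, intention=intention, chosen=chosen
        )
        m, _ = measure_trial(trial, geom)
        assert m.error is is_error

    def test_clean_trial_has_finite_measures(self, geom, small_session):
        _, trials, _ = small_session
        m, npath = measure_trial(trials[0], geom)
        assert np.isfinite([m.it_ms, m.mt_ms, m.auc_xu2]).all()
        assert m.exclusion_reason == "none"
        assert isinstance(npath, NormalizedPath)

    def test_two_sample_window_flagged_too_few_points(self, geom):
        tx, ty = geom.right_target_center
        hx, hy = geom.home_center
        trial = make_trial([(0.0, hx, hy), (40.0, hx + 100, hy - 100), (80.0, tx, ty)])
        m, npath = measure_trial(trial, geom)
        assert m.exclusion_reason == "too_few_points"
        assert npath is None and np.isnan(m.auc_xu2)
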