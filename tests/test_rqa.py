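"""Recurrence engine versus a naive brute-force implementation, plus
windowing and radius calibration."""

import numpy as np
import pytest

from pupilrqa import (
    RQAParams,
    calibrate_radius,
    det,
    diagonal_lines,
    embed,
    ent,
    recurrence_matrix,
    rqa_measures,
    rr,
    windowed_rqa,
)
from pupilrqa.exceptions import (
    CalibrationError,
    InsufficientDataError,
    InvalidSpecError,
    MissingDataError,
)
from pupilrqa.traces import PupilTraceClean, WindowScheme


# ---------------------------------------------------------------------------
# Brute-force oracle: plain Python loops, no shared code with the engine.
# ---------------------------------------------------------------------------

def brute_embed(x, delay, dim):
    n_vec = len(x) - (dim - 1) * delay
    return [[x[i + k * delay] for k in range(dim)] for i in range(n_vec)]


def brute_distance(u, v, norm):
    if norm == "euclidean":
        return sum((a - b) ** 2 for a, b in zip(u, v)) ** 0.5
    return max(abs(a - b) for a, b in zip(u, v))


def brute_rqa(x, delay, dim, radius, min_diag, theiler, norm="euclidean"):
    vecs = brute_embed(list(x), delay, dim)
    n = len(vecs)
    R = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if abs(i - j) >= theiler and brute_distance(vecs[i], vecs[j], norm) <= radius:
                R[i][j] = 1
    eligible = sum(1 for i in range(n) for j in range(n) if abs(i - j) >= theiler)
    n_rec = sum(sum(row) for row in R)
    rr_val = 100.0 * n_rec / eligible if eligible else 0.0

    hist = {}
    for k in range(max(theiler, 0), n):
        run = 0
        for i in range(n - k):
            if R[i][i + k]:
                run += 1
            else:
                if run:
                    hist[run] = hist.get(run, 0) + 1
                run = 0
        if run:
            hist[run] = hist.get(run, 0) + 1

    total_pts = sum(l * c for l, c in hist.items())
    on_lines = sum(l * c for l, c in hist.items() if l >= min_diag)
    det_val = 100.0 * on_lines / total_pts if total_pts else 0.0

    counts = [c for l, c in hist.items() if l >= min_diag]
    if len(counts) <= 1:
        ent_val = 0.0
    else:
        tot = sum(counts)
        ent_val = -sum((c / tot) * np.log(c / tot) for c in counts)
    return rr_val, det_val, ent_val, hist


class TestEmbed:
    def test_vector_count_at_pipeline_parameters(self):
        x = np.random.default_rng(0).standard_normal(500)
        assert embed(x, delay=6, dimension=6).shape == (470, 6)

    def test_dimension_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(embed(x, delay=3, dimension=1).ravel(), x)

    def test_small_worked_example(self):
        out = embed(np.array([1.0, 2.0, 3.0]), delay=1, dimension=2)
        np.testing.assert_array_equal(out, [[1, 2], [2, 3]])

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            embed(np.arange(5.0), delay=3, dimension=3)
        with pytest.raises(MissingDataError):
            embed(np.array([1.0, np.nan, 3.0, 4.0]), delay=1, dimension=2)


class TestRecurrenceMatrix:
    def test_constant_series_fully_recurrent(self):
        states = embed(np.full(20, 0.5), delay=1, dimension=2)
        R = recurrence_matrix(states, radius=0.1, theiler=0)
        assert R.all()
        assert rr(R, theiler=0) == 100.0

    def test_tiny_radius_empty(self):
        states = embed(np.arange(20.0), delay=1, dimension=2)
        R = recurrence_matrix(states, radius=1e-6, theiler=1)
        assert not R.any()
        assert rr(R, theiler=1) == 0.0

    def test_matches_brute_force_matrix(self, rng):
        x = rng.standard_normal(30)
        states = embed(x, delay=2, dimension=3)
        R = recurrence_matrix(states, radius=1.0, theiler=1)
        vecs = brute_embed(list(x), 2, 3)
        for i in range(len(vecs)):
            for j in range(len(vecs)):
                expected = abs(i - j) >= 1 and brute_distance(vecs[i], vecs[j], "euclidean") <= 1.0
                assert R[i, j] == expected


class TestLineMeasures:
    def test_all_zero_matrix_empty_histogram(self):
        R = np.zeros((10, 10), dtype=bool)
        assert diagonal_lines(R, theiler=1) == {}
        assert det({}, 2) == 0.0 and ent({}, 2) == 0.0

    def test_full_matrix_one_line_per_offdiagonal(self):
        k = 8
        R = np.ones((k, k), dtype=bool)
        hist = diagonal_lines(R, theiler=1)
        # offsets 1..k-1 contribute one line each of length k-offset
        assert hist == {length: 1 for length in range(1, k)}

    def test_periodic_series_fully_deterministic(self):
        x = np.tile(np.array([0.0, 0.3, 0.8, 0.4]), 30)
        m = rqa_measures(x, RQAParams(delay=1, dimension=2, radius=0.01, min_diag=4, theiler=1))
        # corner diagonals are truncated below min_diag, so DET is near-100
        assert m.det > 99.0

    def test_entropy_of_two_equal_length_classes(self):
        assert ent({30: 5, 40: 5}, min_diag=25) == pytest.approx(np.log(2))
        assert ent({30: 7}, min_diag=25) == 0.0
        assert ent({10: 5, 40: 5}, min_diag=25) == 0.0  # below-threshold excluded

    def test_det_counts_only_qualifying_lines(self):
        hist = {2: 3, 5: 2}  # 6 points in short lines, 10 in long
        assert det(hist, min_diag=5) == pytest.approx(100.0 * 10 / 16)


class TestOracleEquivalence:
    def test_exact_match_on_random_series(self):
        """Production engine equals the brute-force implementation exactly on
        50 random series of length <= 100 with randomized parameters."""
        rng = np.random.default_rng(2024)
        for case in range(50):
            n = int(rng.integers(30, 101))
            kind = case % 3
            if kind == 0:
                x = rng.standard_normal(n)
            elif kind == 1:
                x = np.cumsum(rng.standard_normal(n))
            else:
                x = np.sin(np.arange(n) / rng.uniform(1, 5)) + 0.1 * rng.standard_normal(n)
            x = (x - x.min()) / (x.max() - x.min())
            delay = int(rng.integers(1, 4))
            dim = int(rng.integers(1, 5))
            if (dim - 1) * delay + 2 > n:
                dim = 2
                delay = 1
            theiler = int(rng.integers(0, 3))
            min_diag = int(rng.integers(2, 6))
            radius = float(rng.uniform(0.05, 0.5))
            norm = "euclidean" if case % 2 else "maximum"
            params = RQAParams(delay=delay, dimension=dim, radius=radius,
                               min_diag=min_diag, theiler=theiler, norm=norm)
            m = rqa_measures(x, params)
            rr_b, det_b, ent_b, hist_b = brute_rqa(
                x, delay, dim, radius, min_diag, theiler, norm)
            assert m.diag_histogram == hist_b, f"case {case}"
            assert m.rr == pytest.approx(rr_b, abs=1e-10), f"case {case}"
            assert m.det == pytest.approx(det_b, abs=1e-10), f"case {case}"
            assert m.ent == pytest.approx(ent_b, abs=1e-10), f"case {case}"


class TestInvariances:
    def test_rr_and_det_nondecreasing_in_radius(self, rng):
        x = np.cumsum(rng.standard_normal(80))
        x = (x - x.min()) / (x.max() - x.min())
        prev_rr, prev_pts = -1.0, -1
        for radius in [0.02, 0.05, 0.1, 0.2, 0.4, 0.8]:
            m = rqa_measures(x, RQAParams(delay=1, dimension=2, radius=radius, min_diag=3))
            assert m.rr >= prev_rr
            assert m.n_recurrent_points >= prev_pts
            prev_rr, prev_pts = m.rr, m.n_recurrent_points

    def test_time_reversal_preserves_rr(self, rng):
        x = np.cumsum(rng.standard_normal(90))
        params = RQAParams(delay=2, dimension=3, radius=0.8, min_diag=3)
        assert rqa_measures(x, params).rr == pytest.approx(
            rqa_measures(x[::-1].copy(), params).rr, abs=1e-10)

    def test_entropy_depends_only_on_length_histogram(self):
        assert ent({26: 4, 31: 2, 50: 2}, 25) == ent({50: 2, 26: 4, 31: 2}, 25)

    def test_invalid_params(self):
        with pytest.raises(InvalidSpecError):
            RQAParams(radius=0.0)
        with pytest.raises(InvalidSpecError):
            RQAParams(min_diag=1)
        with pytest.raises(InvalidSpecError):
            RQAParams(norm="manhattan")


class TestWindowing:
    def test_paper_layout_56_windows(self):
        scheme = WindowScheme(window=500, step=100, last_n_seconds=120.0)
        assert scheme.n_windows(6000, 50.0) == 56
        assert scheme.n_windows(9000, 50.0) == 56  # longer traces: still last 120 s

    def test_single_window_trace(self):
        scheme = WindowScheme(window=500, step=100, span="full")
        assert scheme.n_windows(500, 50.0) == 1

    def test_windows_right_aligned_to_trace_end(self):
        scheme = WindowScheme(window=500, step=100, last_n_seconds=20.0)
        starts = scheme.starts(3000, 50.0)
        assert starts[-1] + 500 == 3000
        assert len(starts) == 6
        assert np.all(np.diff(starts) == 100)

    def test_windowed_rqa_flags_missing_windows(self):
        rng = np.random.default_rng(5)
        values = rng.uniform(0, 1, 1500)
        values[1250:1300] = np.nan
        trace = PupilTraceClean("s", 50.0, values, group="solver", age=8.0)
        scheme = WindowScheme(window=500, step=100, last_n_seconds=20.0)
        df = windowed_rqa(trace, scheme, RQAParams(delay=1, dimension=2, radius=0.2, min_diag=3))
        assert len(df) == 6
        overlapping = df[df.missing]
        assert len(overlapping) > 0
        assert overlapping["ent"].isna().all()
        clean_rows = df[~df.missing]
        assert clean_rows[["rr", "det", "ent"]].notna().all().all()

    def test_stationary_trace_windows_match_full_series(self, rng):
        x = rng.uniform(0, 1, 2000)
        trace = PupilTraceClean("s", 50.0, x)
        scheme = WindowScheme(window=500, step=100, last_n_seconds=40.0)
        params = RQAParams(delay=1, dimension=2, radius=0.3, min_diag=2)
        df = windowed_rqa(trace, scheme, params)
        full = rqa_measures(x, params)
        assert df["rr"].mean() == pytest.approx(full.rr, rel=0.05)

    def test_trace_shorter_than_window_raises(self):
        trace = PupilTraceClean("s", 50.0, np.random.default_rng(0).uniform(0, 1, 300))
        with pytest.raises(InsufficientDataError):
            windowed_rqa(trace, WindowScheme(window=500, step=100),
                         RQAParams(delay=1, dimension=2, radius=0.1, min_diag=3))


class TestCalibration:
    @pytest.fixture(scope="class")
    @staticmethod
    def traces():
        rng = np.random.default_rng(9)
        out = []
        for s in range(4):
            x = np.cumsum(rng.standard_normal(1500))
            x = (x - x.min()) / (x.max() - x.min())
            out.append(PupilTraceClean(f"s{s}", 50.0, x))
        return out

    def test_hits_target_within_tolerance(self, traces):
        scheme = WindowScheme(window=500, step=100, last_n_seconds=20.0)
        params = RQAParams(delay=6, dimension=6, radius=1.0, min_diag=25)
        radius, achieved = calibrate_radius(
            traces, scheme, params, target_rr_percent=10.0, tolerance=1.0,
            subsample_pairs=None)
        assert abs(achieved - 10.0) <= 1.0
        assert radius > 0

    def test_monotone_in_target(self, traces):
        scheme = WindowScheme(window=500, step=100, last_n_seconds=20.0)
        params = RQAParams(delay=6, dimension=6, radius=1.0, min_diag=25)
        r_low, _ = calibrate_radius(traces, scheme, params, target_rr_percent=5.0)
        r_high, _ = calibrate_radius(traces, scheme, params, target_rr_percent=25.0)
        assert r_high > r_low

    def test_target_100_saturates(self, traces):
        scheme = WindowScheme(window=500, step=100, last_n_seconds=20.0)
        params = RQAParams(delay=6, dimension=6, radius=1.0, min_diag=25)
        radius, achieved = calibrate_radius(traces, scheme, params, target_rr_percent=100.0)
        assert achieved == pytest.approx(100.0)

    def test_no_complete_window_fails(self):
        values = np.full(1000, np.nan)
        values[:10] = 0.5
        trace = PupilTraceClean("s", 50.0, values)
        with pytest.raises(CalibrationError):
            calibrate_radius([trace], WindowScheme(window=500, step=100, last_n_seconds=20.0),
                             RQAParams(delay=1, dimension=2, radius=1.0, min_diag=3))
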