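"""Run analytics: pressures, step detection, GPS metrics, survey aggregation."""

import math

import numpy as np
import pytest

from baropod.analytics import (
    EARTH_RADIUS_M,
    EmptyDataError,
    GpsPoint,
    OrderingError,
    RunSession,
    SurveyTable,
    average_pressure,
    detect_steps,
    read_gps_csv,
    read_gpx,
    read_survey_csv,
    summarize_run,
    summarize_survey,
    table4_survey,
    track_metrics,
)
from baropod.simulate import RunnerProfile, SimConfig, simulate_session
from conftest import make_vector


class TestAveragePressure:
    def test_constant_stream(self):
        stream = [make_vector([50] * 16, t_ms=150 * i) for i in range(5)]
        assert average_pressure(stream) == 50.0

    def test_mean_of_per_frame_means(self):
        stream = [
            make_vector([20] * 16, t_ms=0),
            make_vector([40] * 16, t_ms=150),
        ]
        assert average_pressure(stream) == 30.0
        assert average_pressure(stream[:1]) == 20.0

    def test_reorder_invariance_and_bounds(self):
        rng = np.random.default_rng(0)
        stream = [
            make_vector(rng.integers(0, 101, 16), t_ms=150 * i) for i in range(20)
        ]
        shuffled = [stream[i] for i in rng.permutation(20)]
        assert average_pressure(stream) == pytest.approx(average_pressure(shuffled))
        assert 0 <= average_pressure(stream) <= 100

    def test_empty_stream_errors(self):
        with pytest.raises(EmptyDataError):
            average_pressure([])


def _pulse_train(n_pulses, period_frames=6, high_frames=2, amplitude=80):
    """Square-wave stream: n pulses of `high_frames` frames at 150 ms."""
    stream = []
    t = 0
    for _ in range(n_pulses):
        for i in range(period_frames):
            level = amplitude if i < high_frames else 0
            stream.append(make_vector([level] + [0] * 15, t_ms=t))
            t += 150
    return stream


class TestDetectSteps:
    def test_silence_has_no_events(self):
        stream = [make_vector([0] * 16, t_ms=150 * i) for i in range(10)]
        assert detect_steps(stream) == []

    @pytest.mark.parametrize("n", [1, 5, 12])
    def test_pulse_train_counts_pulses(self, n):
        assert len(detect_steps(_pulse_train(n))) == n

    def test_gap_reset_handles_gated_streams(self):
        """Suppressed swing frames leave gaps; each burst is one step."""
        stream = [
            make_vector([70] * 16, t_ms=0),
            make_vector([60] * 16, t_ms=150),   # same stance
            make_vector([75] * 16, t_ms=600),   # next stance after a gap
            make_vector([65] * 16, t_ms=750),
        ]
        assert len(detect_steps(stream)) == 2

    def test_threshold_monotonicity_on_pulse_signals(self):
        """For pulse-shaped (unimodal-per-step) signals, raising the
        threshold can only drop whole pulses, never add events."""
        rng = np.random.default_rng(1)
        stream = []
        t = 0
        for _ in range(15):
            amp = int(rng.integers(30, 101))
            for level in (amp, amp - 5, 0, 0):
                stream.append(make_vector([level] + [0] * 15, t_ms=t))
                t += 150
        counts = [len(detect_steps(stream, on_threshold=th)) for th in range(10, 101, 10)]
        assert counts[0] == 15
        assert all(b <= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] <= counts[0]

    def test_unordered_stream_rejected(self):
        stream = [make_vector([0] * 16, t_ms=300), make_vector([0] * 16, t_ms=150)]
        with pytest.raises(OrderingError):
            detect_steps(stream)


class TestTrackMetrics:
    def test_coincident_points(self):
        track = [GpsPoint(50.0, 19.0, 0), GpsPoint(50.0, 19.0, 1000)]
        dist, speed = track_metrics(track)
        assert dist == 0.0 and speed == 0.0

    def test_one_degree_longitude_on_equator(self):
        track = [GpsPoint(0.0, 0.0, 0), GpsPoint(0.0, 1.0, 1000)]
        dist, _ = track_metrics(track)
        assert dist == pytest.approx(2 * math.pi * EARTH_RADIUS_M / 360, rel=1e-6)

    def test_antipodal_half_circumference(self):
        track = [GpsPoint(0.0, 0.0, 0), GpsPoint(0.0, 180.0, 1000)]
        dist, _ = track_metrics(track)
        assert dist == pytest.approx(math.pi * EARTH_RADIUS_M, rel=1e-6)

    def test_reversal_invariance_and_speed_scaling(self):
        track = [
            GpsPoint(50.0 + i * 1e-4, 19.0 + i * 5e-5, 1000 * i) for i in range(10)
        ]
        rev = [
            GpsPoint(p.lat, p.lon, 1000 * i)
            for i, p in enumerate(reversed(track))
        ]
        d1, s1 = track_metrics(track)
        d2, _ = track_metrics(rev)
        assert d1 == pytest.approx(d2)
        slow = [GpsPoint(p.lat, p.lon, p.t_ms * 2) for p in track]
        _, s_slow = track_metrics(slow)
        assert s_slow == pytest.approx(s1 / 2)

    def test_degenerate_inputs(self):
        with pytest.raises(EmptyDataError):
            track_metrics([GpsPoint(0, 0, 0)])
        with pytest.raises(OrderingError):
            track_metrics([GpsPoint(0, 0, 1000), GpsPoint(0, 0, 0)])


@pytest.fixture(scope="module")
def session():
    return simulate_session(
        RunnerProfile(cadence_spm=180),
        SimConfig(duration_ms=60_000, random_seed=3),
    )


class TestSummarizeRun:

    def test_symmetric_session_balance(self, session):
        summary = summarize_run(session)
        assert abs(summary.balance_ratio - 0.5) < 0.05

    def test_cadence_recovery_within_5_percent(self, session):
        summary = summarize_run(session)
        truth = session.meta["ground_truth"]
        assert summary.step_count == pytest.approx(truth["step_count"], rel=0.05)
        assert summary.cadence_spm == pytest.approx(truth["cadence_spm"], rel=0.05)

    def test_duration_spans_both_streams(self, session):
        summary = summarize_run(session)
        all_t = [v.timestamp_ms for v in session.left + session.right]
        assert summary.duration_ms == max(all_t) - min(all_t)

    def test_empty_foot_stream_names_the_foot(self, session):
        broken = RunSession(left=session.left, right=[], gps_track=session.gps_track)
        with pytest.raises(EmptyDataError, match="right"):
            summarize_run(broken)


class TestSurvey:
    def test_packaged_table_means(self):
        summary = summarize_survey(table4_survey())
        assert list(summary.aspect_means.values()) == [3.9, 4.9, 4.7, 4.8, 4.6, 4.6]
        assert summary.overall_mean == 4.58

    def test_constant_table(self):
        table = SurveyTable(ratings=np.full((4, 3), 5), aspects=("a", "b", "c"))
        summary = summarize_survey(table)
        assert all(m == 5.0 for m in summary.aspect_means.values())
        assert summary.overall_mean == 5.0

    def test_single_rater(self):
        table = SurveyTable(ratings=np.array([[1, 3, 5]]), aspects=("a", "b", "c"))
        assert list(summarize_survey(table).aspect_means.values()) == [1.0, 3.0, 5.0]

    def test_grand_mean_is_mean_of_aspect_means(self):
        rng = np.random.default_rng(2)
        table = SurveyTable(
            ratings=rng.integers(1, 6, size=(7, 4)), aspects=("a", "b", "c", "d")
        )
        summary = summarize_survey(table)
        # exact for rectangular tables, up to the 2-decimal reporting step
        assert summary.overall_mean == pytest.approx(
            np.mean(table.ratings), abs=0.005
        )

    def test_out_of_scale_rating_rejected(self):
        with pytest.raises(ValueError):
            SurveyTable(ratings=np.array([[0, 3]]), aspects=("a", "b"))
        with pytest.raises(EmptyDataError):
            SurveyTable(ratings=np.empty((0, 0)), aspects=())


class TestIO:
    def test_gps_csv_roundtrip(self, tmp_path):
        path = tmp_path / "gps.csv"
        path.write_text("t_ms,lat,lon\n0,50.06,19.94\n1000,50.0601,19.94\n")
        track = read_gps_csv(path)
        assert len(track) == 2
        assert track[1].lat == pytest.approx(50.0601)

    def test_gpx_reader(self, tmp_path):
        gpx = """<?xml version="1.0" encoding="UTF-8"?>
<gpx version="1.1" creator="test" xmlns="http://www.topografix.com/GPX/1/1">
 <trk><trkseg>
  <trkpt lat="50.0600" lon="19.9400"><time>2023-01-01T10:00:00Z</time></trkpt>
  <trkpt lat="50.0605" lon="19.9400"><time>2023-01-01T10:00:30Z</time></trkpt>
 </trkseg></trk>
</gpx>
"""
        path = tmp_path / "run.gpx"
        path.write_text(gpx)
        track = read_gpx(path)
        assert [p.t_ms for p in track] == [0, 30_000]
        dist, speed = track_metrics(track)
        assert dist == pytest.approx(0.0005 * 111_195, rel=1e-3)

    def test_survey_csv_reader(self, tmp_path):
        path = tmp_path / "s.csv"
        path.write_text("rater,A,B\n1,5,4\n2,3,2\n")
        table = read_survey_csv(path)
        assert table.aspects == ("A", "B")
        assert summarize_survey(table).aspect_means == {"A": 4.0, "B": 3.0}
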