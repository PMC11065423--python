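"""Session preprocessing, place-cell classification, stats and trends."""

import numpy as np
import pytest

from driftlab.session import (
    SessionRecording,
    SessionStats,
    classify_place_cells,
    preprocess,
    session_rate_maps,
    session_statistics,
    trend_regression,
)


def make_session(
    animal="a1", day=0, T=3000, n_cells=10, track=100.0, dt=0.1, seed=0,
    tuned=False, width=10.0, speed=None,
):
    """Synthetic fixture: uniform back-and-forth run; optionally Gaussian-tuned cells."""
    rng = np.random.default_rng(seed)
    t = np.arange(T) * dt
    # aperiodic back-and-forth run (periodic running defeats shuffle nulls)
    v = np.abs(rng.normal(12.0, 4.0, T))
    pos = np.empty(T)
    x, d = track / 2, 1.0
    for i in range(T):
        pos[i] = x
        x += d * v[i] * dt
        if x >= track:
            x, d = 2 * track - x, -1.0
        elif x <= 0:
            x, d = -x, 1.0
    spd = v if speed is None else speed
    if tuned:
        centers = rng.uniform(0, track, n_cells)
        rate = 5.0 * np.exp(-((pos[:, None] - centers[None, :]) ** 2) / (2 * width**2))
    else:
        rate = np.full((T, n_cells), 0.5)
    acts = rng.poisson(rate * dt).astype(float)
    return SessionRecording(
        animal=animal, day=day, time=t, position=pos, speed=spd,
        activity=acts, track_length=track,
    )


class TestPreprocess:
    def test_all_slow_frames_is_error(self):
        s = make_session(speed=np.zeros(3000))
        with pytest.raises(ValueError, match="empty"):
            preprocess(s)

    def test_zero_threshold_keeps_moving_frames(self):
        s = make_session()
        out = preprocess(s, speed_threshold=0.0)
        assert out.activity.shape[0] == int((s.speed > 0).sum())

    def test_known_slow_fraction_removed_exactly(self):
        T = 1000
        s = make_session(T=T)
        speed = np.full(T, 10.0)
        slow = np.zeros(T, dtype=bool)
        slow[::4] = True  # exactly 25% slow frames
        speed[slow] = 0.5
        s = SessionRecording(
            animal="a", day=0, time=s.time, position=s.position, speed=speed,
            activity=s.activity, track_length=s.track_length,
        )
        out = preprocess(s, speed_threshold=1.0)
        assert out.activity.shape[0] == T - slow.sum()

    def test_min_rate_drops_silent_cells(self):
        s = make_session(n_cells=4)
        s.activity[:, 2] = 0.0
        out = preprocess(s, speed_threshold=0.0, min_rate=0.1)
        assert out.n_cells == 3
        assert "2" not in [str(c) for c in out.cell_ids]


class TestRateMaps:
    def test_delegation_matches_metrics_module(self):
        from driftlab.metrics import compute_rate_maps

        s = make_session(tuned=True)
        maps = session_rate_maps(s, bin_cm=4.0)
        direct = compute_rate_maps(
            s.activity, s.position, n_bins=25, directions=s.directions,
            pos_range=(0.0, s.track_length),
        )
        np.testing.assert_allclose(maps.rates, direct.rates, equal_nan=True)

    def test_constant_rate_cell_flat_map(self):
        s = make_session(T=20_000, seed=1)
        maps = session_rate_maps(s, bin_cm=10.0)
        visited = maps.visited
        rates = maps.rates[0, visited]
        assert rates.std() / rates.mean() < 0.5  # Poisson noise only


class TestPlaceCellClassification:
    def test_null_calibration_false_positive_rate(self):
        """Position-independent cells should be classified as place cells
        at roughly the nominal 5% rate."""
        s = make_session(T=4000, n_cells=100, seed=2)
        is_pc = classify_place_cells(s, n_shuffles=200, percentile=95, seed=0)
        mc_se = np.sqrt(0.05 * 0.95 / 100)
        assert is_pc.mean() <= 0.05 + 2 * mc_se + 0.02

    def test_sharply_tuned_cells_detected(self):
        s = make_session(T=4000, n_cells=10, tuned=True, width=10.0, seed=3)
        is_pc = classify_place_cells(s, n_shuffles=200, percentile=95, seed=1)
        assert is_pc.mean() >= 0.9

    def test_invalid_shuffle_count_and_short_session(self):
        s = make_session()
        with pytest.raises(ValueError):
            classify_place_cells(s, n_shuffles=0)
        short = make_session(T=150)  # 15 s at 10 Hz < 2 x 10 s minimum shift
        with pytest.raises(ValueError, match="short"):
            classify_place_cells(short, n_shuffles=10)


class TestSessionStatistics:
    def test_single_session_normalizes_to_one(self):
        df = session_statistics([make_session(tuned=True)], mode="active_count")
        assert df.stat_norm.iloc[0] == 1.0 and df.si_norm.iloc[0] == 1.0

    def test_planted_linear_decline_recovered_exactly(self):
        """Cells silenced day by day: normalized active counts reproduce the
        planted staircase exactly."""
        sessions = []
        n = 20
        for day, alive in enumerate([20, 18, 16, 14]):
            s = make_session(day=day, n_cells=n, tuned=True, seed=10 + day)
            s.activity[:, alive:] = 0.0
            sessions.append(s)
        df = session_statistics(sessions, mode="active_count", min_rate=0.01)
        np.testing.assert_allclose(df.stat_norm, [1.0, 0.9, 0.8, 0.7])

    def test_experience_day_pooling(self):
        """Two environments visited on the same experience day pool cells."""
        a = make_session(day=0, n_cells=10, tuned=True, seed=1)
        b = make_session(day=0, n_cells=15, tuned=True, seed=2)
        c = make_session(day=1, n_cells=10, tuned=True, seed=3)
        df = session_statistics([a, b, c], mode="active_count", min_rate=0.01)
        assert df.loc[df.day == 0, "n_active"].iloc[0] == 25

    def test_session_stats_container_validates_normalization(self):
        df = session_statistics(
            [make_session(day=d, tuned=True, seed=d) for d in range(3)],
            mode="active_count", min_rate=0.01,
        )
        SessionStats(table=df)  # valid: first-session values are 1
        bad = df.copy()
        bad["stat_norm"] *= 2.0
        with pytest.raises(ValueError):
            SessionStats(table=bad)

    def test_normalization_idempotent(self):
        df = session_statistics(
            [make_session(day=d, tuned=True, seed=d) for d in range(3)],
            mode="active_count", min_rate=0.01,
        )
        renorm = df.stat_norm / df.stat_norm.iloc[0]
        np.testing.assert_allclose(renorm, df.stat_norm)


class TestTrendRegression:
    def test_exact_linear_series(self):
        t = np.arange(8)
        res = trend_regression(1.0 + 0.5 * t, t)
        assert res.slope == pytest.approx(0.5)
        assert res.p_value < 1e-6
        assert res.n == 8

    def test_constant_series_has_no_trend(self):
        res = trend_regression(np.full(6, 2.0), np.arange(6))
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.9

    def test_planted_slope_recovered_across_replicates(self):
        """slope −0.03 + noise σ=0.05, 8 animals x 8 days."""
        slopes = []
        rng = np.random.default_rng(0)
        for _ in range(50):
            days = np.tile(np.arange(8), 8)
            y = 1.0 - 0.03 * days + rng.normal(0, 0.05, days.size)
            slopes.append(trend_regression(y, days).slope)
        assert np.mean(slopes) == pytest.approx(-0.03, abs=0.01)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(1)
        t = np.arange(10)
        y = 2.0 - 0.1 * t + rng.normal(0, 0.1, 10)
        r1, r3 = trend_regression(y, t), trend_regression(3 * y, t)
        assert r3.slope == pytest.approx(3 * r1.slope)
        assert r3.p_value == pytest.approx(r1.p_value, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            trend_regression([1.0, 2.0], [0, 1])
        with pytest.raises(ValueError):
            trend_regression([1.0, 2.0, 3.0], [5, 5, 5])
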