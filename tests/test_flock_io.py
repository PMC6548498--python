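"""Trajectory I/O, validation and per-bird kinematics."""

import logging

import numpy as np
import pandas as pd
import pytest

from compoundv import flock_io
from compoundv.flock_io import (
    SPECIES,
    BirdTrack,
    DataError,
    FlockRecording,
    SchemaError,
    compute_kinematics,
    read_flock,
    read_flock_wide,
    wingbeat_sample_frames,
    write_flock,
)


def _straight_flock(v=(3.0, 4.0, 0.0), n=30, n_birds=2, frame_rate=29.97):
    dt = 1.0 / frame_rate
    tracks = []
    for b in range(n_birds):
        t = np.arange(n)
        pos = np.outer(t * dt, v) + np.array([b * 2.0, 0.0, 0.0])
        tracks.append(BirdTrack(f"b{b}", SPECIES["godwit"], t, pos))
    return FlockRecording("test", tracks, frame_rate=frame_rate)


class TestReaders:
    def test_empty_table_warns_and_returns_no_tracks(self, caplog):
        df = pd.DataFrame(columns=["bird_id", "frame", "x_m", "y_m", "z_m"])
        with caplog.at_level(logging.WARNING):
            flock = read_flock(df)
        assert flock.n_birds == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_missing_column_names_the_column(self):
        df = pd.DataFrame({"bird_id": ["a"], "frame": [0], "x_m": [0.0], "y_m": [0.0]})
        with pytest.raises(SchemaError, match="z"):
            read_flock(df)

    def test_non_monotone_frames_rejected(self):
        df = pd.DataFrame(
            {"bird_id": ["a"] * 3, "frame": [0, 2, 1], "x_m": 0.0, "y_m": 0.0, "z_m": 0.0}
        )
        with pytest.raises(DataError, match="monotone"):
            read_flock(df)

    def test_single_frame_birds_dropped(self, caplog):
        df = pd.DataFrame(
            {
                "bird_id": ["a", "a", "b"],
                "frame": [0, 1, 0],
                "x_m": [0.0, 0.1, 5.0],
                "y_m": 0.0,
                "z_m": 0.0,
            }
        )
        with caplog.at_level(logging.WARNING):
            flock = read_flock(df)
        assert [t.bird_id for t in flock.tracks] == ["a"]

    def test_header_sniffing_is_case_and_alias_tolerant(self):
        df = pd.DataFrame(
            {"Track": ["a"] * 2, "FRAME": [0, 1], "X": [0.0, 1.0], "y": 0.0, "Z_m": 0.0}
        )
        assert read_flock(df).n_birds == 1

    def test_wide_layout_reader(self):
        df = pd.DataFrame(
            {
                "frame": [0, 1, 2],
                "a_x": [0.0, 1.0, 2.0],
                "a_y": 0.0,
                "a_z": 0.0,
                "b_x": [5.0, 6.0, 7.0],
                "b_y": 1.0,
                "b_z": 0.0,
            }
        )
        flock = read_flock_wide(df)
        assert flock.n_birds == 2
        np.testing.assert_allclose(flock.track("a").positions[:, 0], [0, 1, 2])

    def test_round_trip_preserves_positions_exactly(self, tmp_path, rng):
        flock = _straight_flock()
        for t in flock.tracks:
            t.positions += rng.normal(0, 1, t.positions.shape)
        path = tmp_path / "traj.csv"
        write_flock(flock, path)
        back = read_flock(path)
        for t in flock.tracks:
            np.testing.assert_array_equal(back.track(t.bird_id).positions, t.positions)
            np.testing.assert_array_equal(back.track(t.bird_id).frames, t.frames)

    def test_gap_longer_than_four_frames_rejected(self):
        with pytest.raises(DataError, match="gap"):
            BirdTrack("a", SPECIES["godwit"], np.array([0, 1, 8]), np.zeros((3, 3)))

    def test_species_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "name": ["godwit", "dunlin"],
                "wingspan_m": [0.78, 0.34],
                "mass_g": [370, 56],
                "default_wingbeat_hz": [6.63, None],
            }
        )
        path = tmp_path / "species.csv"
        df.to_csv(path, index=False)
        table = flock_io.read_species_table(path)
        assert table["godwit"].wingspan == 0.78
        assert table["dunlin"].default_wingbeat_hz is None


class TestKinematics:
    def test_stationary_bird_zero_speeds(self):
        tr = BirdTrack("a", SPECIES["godwit"], np.arange(10), np.ones((10, 3)))
        kin = compute_kinematics(FlockRecording("f", [tr]))
        assert np.allclose(kin["ground_speed"], 0)
        assert np.allclose(kin["z_speed"], 0)
        assert np.allclose(kin["turn_rate"], 0)

    def test_straight_line_pythagorean_speed(self):
        kin = compute_kinematics(_straight_flock(v=(3.0, 4.0, 0.0)))
        assert np.allclose(kin["ground_speed"], 5.0, atol=1e-9)
        assert np.allclose(kin["heading_deg"], 53.130102, atol=1e-6)
        assert np.allclose(kin["turn_rate"], 0, atol=1e-6)

    def test_circular_path_turn_rate_matches_angular_rate(self):
        """Closed-form circle: turn rate equals omega in deg/s, checked
        against the numeric differencing path on a 100-frame circle."""
        frame_rate = 29.97
        omega = 1.2  # rad/s
        t = np.arange(100) / frame_rate
        pos = np.column_stack([10 * np.cos(omega * t), 10 * np.sin(omega * t), 0 * t])
        tr = BirdTrack("a", SPECIES["godwit"], np.arange(100), pos)
        kin = compute_kinematics(FlockRecording("f", [tr], frame_rate=frame_rate))
        interior = kin.iloc[2:-2]
        assert np.allclose(interior["turn_rate"], np.degrees(omega), rtol=1e-3)
        assert np.allclose(interior["ground_speed"], 10 * omega, rtol=1e-3)

    def test_rotation_equivariance(self, rng):
        """Rotating positions about z rotates headings and leaves speeds
        and turn rates unchanged."""
        flock = _straight_flock()
        for t in flock.tracks:
            t.positions += rng.normal(0, 0.1, t.positions.shape)
        kin0 = compute_kinematics(flock)
        theta = np.deg2rad(37.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for t in flock.tracks:
            t.positions[:, :2] = t.positions[:, :2] @ R.T
        kin1 = compute_kinematics(flock)
        np.testing.assert_allclose(kin1["ground_speed"], kin0["ground_speed"], atol=1e-9)
        np.testing.assert_allclose(kin1["turn_rate"], kin0["turn_rate"], atol=1e-6)
        dh = (kin1["heading_deg"] - kin0["heading_deg"]) % 360
        np.testing.assert_allclose(dh, 37.0, atol=1e-9)

    def test_time_dilation_scales_rates(self):
        """The same per-frame positions replayed at half the frame rate
        halve all speeds and turn rates."""
        f1 = _straight_flock(frame_rate=29.97)
        f2 = FlockRecording("half", f1.tracks, frame_rate=29.97 / 2)
        k1 = compute_kinematics(f1)
        k2 = compute_kinematics(f2)
        np.testing.assert_allclose(k2["ground_speed"], k1["ground_speed"] / 2,
                                   atol=1e-12)
        np.testing.assert_allclose(k2["turn_rate"], k1["turn_rate"] / 2, atol=1e-9)

    def test_short_tracks_excluded(self):
        tr = BirdTrack("a", SPECIES["godwit"], np.arange(2), np.zeros((2, 3)))
        kin = compute_kinematics(FlockRecording("f", [tr]))
        assert kin.empty


class TestWingbeatSampling:
    def test_six_hz_every_fifth_frame(self):
        flock = _straight_flock(n=30)
        frames = wingbeat_sample_frames(flock, {"b0": 6.0, "b1": 6.0})
        np.testing.assert_array_equal(frames["b0"], np.arange(0, 30, 5))

    def test_frequency_at_or_above_frame_rate_clamps_to_every_frame(self, caplog):
        flock = _straight_flock(n=10)
        with caplog.at_level(logging.WARNING):
            frames = wingbeat_sample_frames(flock, {"b0": 60.0, "b1": 60.0})
        np.testing.assert_array_equal(frames["b0"], np.arange(10))
        assert any("frame rate" in r.message for r in caplog.records)

    def test_non_positive_frequency_raises(self):
        with pytest.raises(ValueError):
            wingbeat_sample_frames(_straight_flock(), {"b0": 0.0, "b1": 6.0})

    def test_wingbeat_sampled_medians_match_full_sampling(self, small_flock):
        """Sampling every wingbeat barely changes the speed medians
        relative to sampling every frame (robustness of the scheme)."""
        flock, _, kin, sample = small_flock
        keep = pd.concat(
            [kin[(kin["bird_id"] == b) & kin["frame"].isin(f)] for b, f in sample.items()]
        )
        med_sampled = keep["ground_speed"].median()
        med_all = kin["ground_speed"].median()
        assert med_sampled == pytest.approx(med_all, rel=0.02)
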