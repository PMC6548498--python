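"""Nearest-neighbor offsets, modal position, non-dimensionalization and
the spacing comparisons."""

import numpy as np
import pandas as pd
import pytest

from compoundv import neighbors
from compoundv.flock_io import SPECIES, BirdTrack, FlockRecording, compute_kinematics
from compoundv.neighbors import (
    InsufficientDataError,
    compare_lateral_by_neighbor_species,
    cross_flock_scaling_regression,
    modal_position,
    nearest_neighbor_offsets,
    pair_wingspan,
    partition_by_elevation,
)


def _flock_from_positions(positions, v=(0.0, 10.0, 0.0), species=None, n_frames=5):
    """Birds at fixed relative positions translating with velocity v."""
    species = species or [SPECIES["godwit"]] * len(positions)
    dt = 1.0 / 29.97
    tracks = []
    for i, p in enumerate(positions):
        t = np.arange(n_frames)
        pos = np.asarray(p, float) + np.outer(t * dt, v)
        tracks.append(BirdTrack(f"b{i}", species[i], t, pos))
    return FlockRecording("f", tracks)


class TestOffsets:
    def test_neighbor_directly_right(self):
        flock = _flock_from_positions([(0, 0, 0), (1, 0, 0)])
        kin = compute_kinematics(flock)
        off = nearest_neighbor_offsets(flock, kin)
        row = off[off["focal_id"] == "b0"].iloc[0]
        assert row["front_back"] == pytest.approx(0.0, abs=1e-9)
        assert row["lateral_signed"] == pytest.approx(1.0, abs=1e-9)
        assert row["elevation"] == pytest.approx(0.0, abs=1e-9)

    def test_neighbor_ahead_left_gives_45_degrees(self):
        ws = 0.78
        flock = _flock_from_positions([(0, 0, 0), (-ws, ws, 0)])
        kin = compute_kinematics(flock)
        off = nearest_neighbor_offsets(flock, kin)
        row = off[off["focal_id"] == "b0"].iloc[0]
        assert row["lateral_signed"] < 0
        assert np.degrees(
            np.arctan2(row["lateral_abs_ws"], row["front_back_ws"])
        ) == pytest.approx(45.0, abs=1e-6)
        assert row["leading"]

    def test_offset_decomposition_preserves_norm(self, small_flock):
        flock, _, kin, sample = small_flock
        off = nearest_neighbor_offsets(flock, kin, sample)
        norm = np.sqrt(
            off["front_back"] ** 2 + off["lateral_signed"] ** 2 + off["elevation"] ** 2
        )
        np.testing.assert_allclose(norm, off["distance3d"], atol=1e-9)

    def test_matches_exhaustive_pairwise_scan(self, small_flock):
        """Nearest-neighbor relation equals an O(n^2) scan per frame."""
        flock, _, kin, _ = small_flock
        off = nearest_neighbor_offsets(flock, kin)
        frame = off["frame"].iloc[0]
        sub = kin[kin["frame"] == frame].reset_index(drop=True)
        pos = sub[["x", "y", "z"]].to_numpy()
        for _, row in off[off["frame"] == frame].iterrows():
            i = sub.index[sub["bird_id"] == row["focal_id"]][0]
            d = np.linalg.norm(pos - pos[i], axis=1)
            d[i] = np.inf
            assert sub["bird_id"].iloc[np.argmin(d)] == row["neighbor_id"]
            assert row["distance3d"] == pytest.approx(d.min(), abs=1e-12)

    def test_slow_focal_birds_skipped(self):
        flock = _flock_from_positions([(0, 0, 0), (1, 0, 0)], v=(0.0, 0.2, 0.0))
        kin = compute_kinematics(flock)
        off = nearest_neighbor_offsets(flock, kin)
        assert off.empty

    def test_leading_restriction_picks_nearest_bird_ahead(self):
        # nearest overall is behind; nearest *leading* is farther but ahead
        flock = _flock_from_positions([(0, 0, 0), (0, -0.5, 0), (0.8, 0.8, 0)])
        kin = compute_kinematics(flock)
        any_nn = nearest_neighbor_offsets(flock, kin)
        lead_nn = nearest_neighbor_offsets(flock, kin, restrict="leading")
        row_any = any_nn[any_nn["focal_id"] == "b0"].iloc[0]
        row_lead = lead_nn[lead_nn["focal_id"] == "b0"].iloc[0]
        assert row_any["neighbor_id"] == "b1"
        assert row_lead["neighbor_id"] == "b2"
        assert row_lead["leading"]


class TestElevationPartition:
    def test_all_zero_elevations_fraction_one(self):
        off = pd.DataFrame({"elevation_ws": np.zeros(10)})
        _, _, frac = partition_by_elevation(off)
        assert frac == 1.0

    def test_gaussian_elevations_match_normal_cdf(self, rng):
        """In-slice fraction of N(0,1) wingspan elevations equals
        P(|Z| <= 1) = 0.683 (normal-CDF oracle)."""
        off = pd.DataFrame({"elevation_ws": rng.normal(0, 1, 2000)})
        _, _, frac = partition_by_elevation(off)
        assert frac == pytest.approx(0.6827, abs=0.03)


class TestModalPosition:
    def test_point_mass_recovered(self):
        off = pd.DataFrame(
            {
                "lateral_abs_ws": np.full(50, 1.0),
                "front_back_ws": np.full(50, 0.8),
                "elevation_ws": np.zeros(50),
                "leading": True,
                "distance3d": np.full(50, 1.28),
            }
        )
        mode = modal_position(off)
        assert mode.lateral_mode == pytest.approx(1.0, abs=0.051)
        assert mode.front_back_mode == pytest.approx(0.8, abs=0.051)
        assert mode.alignment_angle == pytest.approx(51.3, abs=3.0)

    def test_heavier_cluster_wins_vs_brute_force_kde(self, rng):
        n = 1000
        pick = rng.random(n) < 0.7
        lat = np.where(pick, rng.normal(1.0, 0.1, n), rng.normal(2.0, 0.1, n))
        fb = np.where(pick, rng.normal(0.8, 0.1, n), rng.normal(1.6, 0.1, n))
        off = pd.DataFrame(
            {
                "lateral_abs_ws": np.abs(lat),
                "front_back_ws": fb,
                "elevation_ws": np.zeros(n),
                "leading": True,
                "distance3d": np.hypot(lat, fb),
            }
        )
        mode = modal_position(off)
        # brute-force: evaluate the same fixed-bandwidth density pointwise
        gx = np.arange(lat.min(), lat.max(), 0.01)
        gy = np.arange(fb.min(), fb.max(), 0.01)
        best, bx, by = -1.0, None, None
        for x in gx:
            dens = np.exp(
                -0.5 * (((x - np.abs(lat)) / 0.25) ** 2)[None, :]
                - 0.5 * (((gy[:, None] - fb[None, :]) / 0.25) ** 2)
            ).sum(axis=1)
            k = np.argmax(dens)
            if dens[k] > best:
                best, bx, by = dens[k], x, gy[k]
        assert mode.lateral_mode == pytest.approx(bx, abs=0.051)
        assert mode.front_back_mode == pytest.approx(by, abs=0.051)
        assert mode.lateral_mode == pytest.approx(1.0, abs=0.1)

    def test_scale_equivariance(self, rng):
        lat = rng.normal(1.0, 0.2, 400)
        fb = rng.normal(0.8, 0.2, 400)
        off = pd.DataFrame(
            {
                "lateral_abs_ws": np.abs(lat),
                "front_back_ws": fb,
                "elevation_ws": np.zeros(400),
                "leading": True,
                "distance3d": np.hypot(lat, fb),
            }
        )
        m1 = modal_position(off, bandwidth=0.25, grid_res=0.05)
        off3 = off.copy()
        off3[["lateral_abs_ws", "front_back_ws", "distance3d"]] *= 3.0
        m3 = modal_position(off3, bandwidth=0.75, grid_res=0.15)
        assert m3.lateral_mode == pytest.approx(3 * m1.lateral_mode, rel=1e-9)
        assert m3.front_back_mode == pytest.approx(3 * m1.front_back_mode, rel=1e-9)

    def test_mode_stays_in_sample_hull_as_bandwidth_grows(self, rng):
        lat = np.abs(rng.normal(1.0, 0.3, 200))
        fb = rng.normal(0.8, 0.3, 200)
        off = pd.DataFrame(
            {
                "lateral_abs_ws": lat,
                "front_back_ws": fb,
                "elevation_ws": np.zeros(200),
                "leading": True,
                "distance3d": np.hypot(lat, fb),
            }
        )
        for bw in (0.1, 0.25, 0.5, 1.0, 2.0):
            m = modal_position(off, bandwidth=bw)
            assert lat.min() - 1e-9 <= m.lateral_mode <= lat.max() + 1e-9
            assert fb.min() - 1e-9 <= m.front_back_mode <= fb.max() + 1e-9

    def test_insufficient_data_raises(self):
        off = pd.DataFrame(
            {
                "lateral_abs_ws": [1.0] * 5,
                "front_back_ws": [0.8] * 5,
                "elevation_ws": [0.0] * 5,
                "leading": [True] * 5,
                "distance3d": [1.28] * 5,
            }
        )
        with pytest.raises(InsufficientDataError):
            modal_position(off)


class TestNondimensionalization:
    def test_conspecific_pair_uses_species_wingspan(self):
        # 0.76 m between godwits is 0.97 godwit wingspans
        assert 0.76 / pair_wingspan(0.78, 0.78) == pytest.approx(0.97, abs=0.005)

    def test_mixed_pair_uses_average_wingspan(self):
        # 0.58 m between a dowitcher and a godwit is 0.89 average wingspans
        assert 0.58 / pair_wingspan(0.52, 0.78) == pytest.approx(0.89, abs=0.005)

    def test_unit_wingspan_identity(self):
        assert pair_wingspan(1.0, 1.0) == 1.0

    def test_offsets_table_scaling(self):
        godwit, dow = SPECIES["godwit"], SPECIES["dowitcher"]
        flock = _flock_from_positions(
            [(0, 0, 0), (0.58, 0, 0)], species=[godwit, dow]
        )
        kin = compute_kinematics(flock)
        off = nearest_neighbor_offsets(flock, kin)
        row = off[off["focal_id"] == "b0"].iloc[0]
        assert row["pair_wingspan"] == pytest.approx(0.65)
        assert row["lateral_abs_ws"] == pytest.approx(0.89, abs=0.005)
        assert row["nn_species_code"] == -1


class TestRankSum:
    def test_identical_groups_give_central_u(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        u, n1, n2, p = compare_lateral_by_neighbor_species(a, list(a))
        assert u == pytest.approx(len(a) ** 2 / 2)
        assert p == pytest.approx(1.0)

    def test_fully_separated_groups_match_exhaustive_count(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        u, n1, n2, p = compare_lateral_by_neighbor_species(a, b)
        brute = sum(x > y for x in a for y in b) + 0.5 * sum(x == y for x in a for y in b)
        assert u == brute == 0

    def test_u_equals_exhaustive_pair_count(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.5, 1, 40)
        u, *_ = compare_lateral_by_neighbor_species(a, b)
        brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert u == pytest.approx(brute)

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_lateral_by_neighbor_species([], [1.0])


class TestScalingRegression:
    def test_exact_proportionality(self):
        x = np.array([0.34, 0.52, 0.72, 0.78])
        res = cross_flock_scaling_regression(0.85 * x, x)
        assert res["slope"] == pytest.approx(0.85, abs=1e-9)
        assert res["r2"] == pytest.approx(1.0)

    def test_scaled_rule_has_zero_slope_across_species(self):
        """Noise-free flocks of all four species at a one-wingspan rule:
        the wingspan-scaled modal lateral is 1.0 for every species, so the
        regression of scaled mode on wingspan has slope ~0."""
        from compoundv.synthetic import SyntheticTruth, generate_compound_v

        modes, spans = [], []
        for sp in ("dunlin", "dowitcher", "avocet", "godwit"):
            truth = SyntheticTruth(lateral_sd=0.0, trailing_sd=0.0, elevation_sd=0.0,
                                   jitter_sd=0.0, seed=1)
            flock, _ = generate_compound_v(30, sp, truth, duration_s=1.0)
            kin = compute_kinematics(flock)
            off = nearest_neighbor_offsets(flock, kin, restrict="leading")
            modes.append(modal_position(off).lateral_mode)
            spans.append(SPECIES[sp].wingspan)
        assert np.allclose(modes, 1.0, atol=0.051)
        res = cross_flock_scaling_regression(modes, spans)
        assert abs(res["slope"]) < 0.15

    def test_degenerate_predictor_raises(self):
        with pytest.raises(ValueError):
            cross_flock_scaling_regression([1, 2, 3], [1.0, 1.0, 1.0])
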