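"""LAP linking: assignment oracle, gating, track assembly, gap closing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from chlamytrack import (
    InfeasibleAssignmentError,
    Link,
    LinkingConfig,
    Track,
    ValidationError,
    build_cost_matrix,
    build_tracks,
    close_gaps,
    link_frames,
    solve_assignment,
)
from chlamytrack.detect import Spot

from conftest import brute_force_assignment


def spot(sid, frame, x, y, r=5.0, q=1.0):
    return Spot(spot_id=sid, frame=frame, x_px=x, y_px=y, radius_px=r, quality=q)


CFG = LinkingConfig(max_link_distance_um=10.0)


class TestBuildCostMatrix:
    def test_empty_lists_give_empty_matrix(self):
        mat = build_cost_matrix([], [], CFG, 1.0)
        assert mat.shape == (0, 0)
        assert solve_assignment(mat) == ([], 0.0)

    def test_coincident_pair_costs_zero(self):
        mat = build_cost_matrix([spot(0, 0, 5, 5)], [spot(1, 1, 5, 5)], CFG, 1.0)
        assert mat.shape == (2, 2)
        assert mat[0, 0] == 0.0

    def test_pair_beyond_gate_forbidden(self):
        mat = build_cost_matrix([spot(0, 0, 0, 0)], [spot(1, 1, 50, 0)], CFG, 1.0)
        assert np.isinf(mat[0, 0])
        # only the no-link alternatives remain feasible
        pairs, _ = solve_assignment(mat)
        assert pairs == [(0, 1), (1, 0)]

    def test_cost_is_squared_distance_in_um2(self):
        mat = build_cost_matrix([spot(0, 0, 0, 0)], [spot(1, 1, 3, 4)], CFG, 0.5)
        assert mat[0, 0] == pytest.approx((5 * 0.5) ** 2)


class TestSolveAssignment:
    def test_one_by_one(self):
        pairs, total = solve_assignment(np.array([[7.0]]))
        assert pairs == [(0, 0)] and total == 7.0

    def test_two_by_two_example(self):
        pairs, total = solve_assignment(np.array([[1.0, 2.0], [2.0, 1.0]]))
        assert pairs == [(0, 0), (1, 1)] and total == 2.0

    def test_rectangular_rejected(self):
        with pytest.raises(ValidationError, match="square"):
            solve_assignment(np.ones((2, 3)))

    def test_all_forbidden_is_infeasible(self):
        with pytest.raises(InfeasibleAssignmentError):
            solve_assignment(np.full((2, 2), np.inf))

    def test_ties_break_lexicographically(self):
        # both diagonals are optimal; the row-0 -> col-0 matching must win
        pairs, total = solve_assignment(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert pairs == [(0, 0), (1, 1)] and total == 2.0

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = rng.integers(2, 7)
            cost = rng.uniform(0, 100, size=(n, n))
            _, total = solve_assignment(cost)
            assert total == pytest.approx(brute_force_assignment(cost))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(arrays(np.float64, (5, 5), elements=st.floats(0, 1000)))
    def test_property_never_beats_brute_force(self, cost):
        _, total = solve_assignment(cost)
        assert total == pytest.approx(brute_force_assignment(cost), rel=1e-9, abs=1e-9)


class TestLinkFrames:
    def test_two_stationary_spots_five_frames(self):
        spots_by_frame = [
            [spot(2 * t, t, 10, 10), spot(2 * t + 1, t, 40, 40)] for t in range(5)
        ]
        links = link_frames(spots_by_frame, CFG, 1.0)
        assert len(links) == 8  # 2 spots x 4 transitions
        assert all(lk.cost == 0.0 for lk in links)

    def test_crossing_particles_minimize_total_displacement(self):
        # two particles approach and pass: LAP must pick the matching with
        # the smaller summed squared displacement (straight-through here)
        f0 = [spot(0, 0, 10, 20), spot(1, 0, 18, 20)]
        f1 = [spot(2, 1, 13, 20), spot(3, 1, 15, 20)]
        links = link_frames([f0, f1], CFG, 1.0)
        matched = {(lk.spot_a_id, lk.spot_b_id) for lk in links}
        # brute force over both matchings: straight (0-2, 1-3) costs 9+9=18,
        # swapped (0-3, 1-2) costs 25+25=50
        assert matched == {(0, 2), (1, 3)}

    def test_no_spot_within_gate_means_death(self):
        f0 = [spot(0, 0, 0, 0)]
        f1 = [spot(1, 1, 100, 100)]
        assert link_frames([f0, f1], CFG, 1.0) == []

    def test_input_order_does_not_change_links(self):
        rng = np.random.default_rng(5)
        f0 = [spot(i, 0, *rng.uniform(0, 100, 2)) for i in range(8)]
        f1 = [spot(10 + i, 1, *rng.uniform(0, 100, 2)) for i in range(8)]
        cfg = LinkingConfig(max_link_distance_um=200.0)
        base = {(lk.spot_a_id, lk.spot_b_id) for lk in link_frames([f0, f1], cfg, 1.0)}
        perm = {(lk.spot_a_id, lk.spot_b_id)
                for lk in link_frames([f0[::-1], f1[::-1]], cfg, 1.0)}
        assert base == perm


class TestBuildTracks:
    def test_chain_of_four_links_one_track(self):
        frames = [[spot(t, t, 10 + t, 10)] for t in range(5)]
        links = [Link(t, t + 1, 1.0) for t in range(4)]
        tracks = build_tracks(links, frames)
        assert len(tracks) == 1
        assert tracks[0].n_spots == 5

    def test_no_links_no_tracks(self):
        frames = [[spot(0, 0, 1, 1)], [spot(1, 1, 90, 90)]]
        assert build_tracks([], frames) == []

    def test_two_disjoint_chains(self):
        frames = [
            [spot(0, 0, 10, 10), spot(1, 0, 50, 50)],
            [spot(2, 1, 11, 10), spot(3, 1, 51, 50)],
        ]
        links = [Link(0, 2, 1.0), Link(1, 3, 1.0)]
        tracks = build_tracks(links, frames)
        assert len(tracks) == 2
        assert tracks[0].track_id != tracks[1].track_id

    def test_spot_conservation(self):
        frames = [
            [spot(0, 0, 10, 10), spot(1, 0, 50, 50)],
            [spot(2, 1, 11, 10)],
        ]
        links = link_frames(frames, CFG, 1.0)
        tracks = build_tracks(links, frames)
        in_tracks = sum(t.n_spots for t in tracks)
        assert in_tracks + (3 - in_tracks) == 3  # every spot in <= 1 track
        ids = [s.spot_id for t in tracks for s in t.spots]
        assert len(ids) == len(set(ids))


class TestCloseGaps:
    def track_pair(self):
        a = Track(0, [spot(0, 8, 10, 10), spot(1, 9, 11, 10), spot(2, 10, 12, 10)])
        b = Track(1, [spot(3, 12, 12.5, 10), spot(4, 13, 13, 10), spot(5, 14, 14, 10)])
        return [a, b]

    def test_merge_across_one_frame_gap(self):
        cfg = LinkingConfig(max_link_distance_um=10.0, max_gap_frames=2)
        merged = close_gaps(self.track_pair(), cfg, 1.0)
        assert len(merged) == 1
        assert merged[0].n_spots == 6

    def test_disabled_by_default(self):
        merged = close_gaps(self.track_pair(), CFG, 1.0)
        assert len(merged) == 2

    def test_blinking_particle_recovered_as_one_track(self):
        # a detection dropout in one middle frame splits a trajectory; the
        # second LAP stage must rejoin the fragments
        frames = [[spot(t, t, 10.0 + t, 20.0)] for t in range(7)]
        frames[3] = []  # dropout
        cfg = LinkingConfig(max_link_distance_um=10.0, max_gap_frames=1)
        links = link_frames(frames, cfg, 1.0)
        tracks = build_tracks(links, frames)
        assert len(tracks) == 2
        closed = close_gaps(tracks, cfg, 1.0)
        assert len(closed) == 1
        assert [s.frame for s in closed[0].spots] == [0, 1, 2, 4, 5, 6]
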