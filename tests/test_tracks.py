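"""Track I/O round trips, filters, clash/fragment joining, temperature lookup."""

import itertools

import numpy as np
import pytest

from larvathermo import tracks as tm
from larvathermo.thermalqc import ThermalFrameSeries
from larvathermo.tracks import Track, tracks_equal

from conftest import straight_track


def _track_from_points(tid, t, pts, head_offset=(2.0, 0.0)):
    pts = np.asarray(pts, dtype=float)
    return Track(id=tid, t=np.asarray(t, dtype=float), centroid=pts,
                 head=pts + np.asarray(head_offset), bend_deg=np.zeros(len(pts)))


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

class TestFimtrackCsv:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(7)
        orig = []
        for tid in range(12):
            n = int(rng.integers(5, 200))
            t = (np.arange(n) + int(rng.integers(0, 50))) / 10.0
            c = rng.uniform(0, 170, (n, 2))
            h = np.clip(c + rng.normal(0, 1, (n, 2)), 0, 170)
            orig.append(Track(id=tid, t=t, centroid=c, head=h,
                              bend_deg=rng.uniform(0, 90, n)))
        path = tmp_path / "tracks.csv"
        tm.write_fimtrack_csv(orig, path)
        back = tm.read_fimtrack_csv(path)
        assert len(back) == len(orig)
        for a, b in zip(orig, back):
            assert tracks_equal(a, b)

    def test_empty_set_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.csv"
        tm.write_fimtrack_csv([], path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1
        assert lines[0].split(",") == tm.FIMTRACK_COLUMNS
        assert tm.read_fimtrack_csv(path) == []

    def test_one_track_three_frames_three_rows(self, tmp_path):
        tr = _track_from_points(0, [0.0, 0.1, 0.2], [(1, 1), (2, 2), (3, 3)])
        path = tmp_path / "t.csv"
        tm.write_fimtrack_csv([tr], path)
        assert len(path.read_text().strip().splitlines()) == 4  # header + 3

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,id,mom_x,mom_y,head_x,head_y,bending\n"
                        "0,0,1.0,1.0,2.0,1.0,0.0\n"
                        "1,0,oops,1.0,2.0,1.0,0.0\n")
        with pytest.raises(ValueError, match="line 3"):
            tm.read_fimtrack_csv(path)


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

class TestFilters:
    @pytest.mark.parametrize("duration_s,kept", [(9.9, False), (10.0, True),
                                                 (25.0, True)])
    def test_short_filter_boundary(self, duration_s, kept):
        n = int(round(duration_s * 10)) + 1  # duration = (n-1)/10
        tr = _track_from_points(0, np.arange(n) / 10.0,
                                np.column_stack([np.arange(n) * 0.1,
                                                 np.zeros(n)]))
        assert tr.duration_s == pytest.approx(duration_s)
        assert (len(tm.filter_short([tr])) == 1) is kept

    def test_short_filter_empty_input(self):
        assert tm.filter_short([]) == []

    @pytest.mark.parametrize("cum,net,kept", [
        (0.4, 0.2, False),   # both below threshold -> non-mover
        (0.4, 0.4, True),    # only one criterion met -> kept
        (10.0, 5.0, True),
    ])
    def test_nonmover_filter(self, cum, net, kept):
        # out-and-back path: go to net, return, pad remaining cum in place
        n_out = 50
        t = np.arange(2 * n_out) / 10.0
        out = np.linspace(0, net, n_out)
        back_to = 2.0 * net - cum  # return leg uses the remaining path budget
        back = np.linspace(net, back_to, n_out)
        x = np.concatenate([out, back])
        tr = _track_from_points(0, t, np.column_stack([x, np.zeros_like(x)]))
        assert tr.path_length_mm() == pytest.approx(cum)
        assert tr.max_displacement_mm() == pytest.approx(net)
        assert (len(tm.filter_nonmoving([tr])) == 1) is kept

    def test_filters_order_independent(self):
        rng = np.random.default_rng(3)
        trs = []
        for tid in range(20):
            n = int(rng.integers(30, 300))
            scale = rng.choice([0.001, 0.5])
            pts = np.cumsum(rng.normal(0, scale, (n, 2)), axis=0) + 50
            trs.append(_track_from_points(tid, np.arange(n) / 10.0, pts))
        ref = {tr.id for tr in tm.filter_nonmoving(tm.filter_short(trs))}
        for perm in [trs[::-1], sorted(trs, key=lambda x: -x.id)]:
            got = {tr.id for tr in tm.filter_nonmoving(tm.filter_short(perm))}
            assert got == ref


# ---------------------------------------------------------------------------
# Clash joining
# ---------------------------------------------------------------------------

def _brute_force_pairing(enders, starters):
    """Oracle: over all one-to-one pairings, minimize total (dt, then dd)."""
    best = None
    for perm in itertools.permutations(starters, len(enders)):
        tot_dt = sum(y.t[0] - x.t[-1] for x, y in zip(enders, perm))
        tot_dd = sum(np.linalg.norm(y.centroid[0] - x.centroid[-1])
                     for x, y in zip(enders, perm))
        key = (tot_dt, tot_dd)
        if best is None or key < best[0]:
            best = (key, list(zip(enders, perm)))
    return best[1]


class TestJoinClashes:
    def _clash_fixture(self):
        # A, B end on frame 1000; C starts frame 1001 at A's endpoint,
        # D starts frame 1001 at B's endpoint
        tA = np.arange(0, 1001) / 10.0
        tC = np.arange(1001, 2000) / 10.0
        A = _track_from_points(0, tA, np.column_stack([np.linspace(10, 60, 1001),
                                                       np.full(1001, 40.0)]))
        B = _track_from_points(1, tA, np.column_stack([np.linspace(150, 100, 1001),
                                                       np.full(1001, 120.0)]))
        C = _track_from_points(2, tC, np.column_stack([np.linspace(60.1, 90, 999),
                                                       np.full(999, 40.0)]))
        D = _track_from_points(3, tC, np.column_stack([np.linspace(99.9, 70, 999),
                                                       np.full(999, 120.0)]))
        return A, B, C, D

    def test_two_way_clash_resolves_to_nearest(self):
        A, B, C, D = self._clash_fixture()
        joined = tm.join_clashes([A, B, C, D])
        assert len(joined) == 2
        by_id = {tr.id: tr for tr in joined}
        assert by_id[0].source_ids == [0, 2]   # A + C
        assert by_id[1].source_ids == [1, 3]   # B + D
        # agrees with the brute-force minimal-gap pairing
        oracle = _brute_force_pairing([A, B], [C, D])
        assert {(x.id, y.id) for x, y in oracle} == {(0, 2), (1, 3)}

    def test_no_simultaneous_endings_is_identity(self):
        trs = [straight_track(tid=i, duration_s=20 + 5 * i, start=(10 + 20 * i, 10))
               for i in range(3)]
        joined = tm.join_clashes(trs)
        assert [tr.id for tr in joined] == [0, 1, 2]
        assert all(len(tr.source_ids) == 1 for tr in joined)

    def test_partial_clash_joins_reciprocal_pair_only(self):
        A, B, C, _ = self._clash_fixture()
        joined = tm.join_clashes([A, B, C])
        by_id = {tr.id: tr for tr in joined}
        assert by_id[0].source_ids == [0, 2]  # A is reciprocally closest to C
        assert by_id[1].source_ids == [1]     # B stays unjoined
        # oracle over the two candidate pairings (A+C vs B+C): A wins on distance
        dA = np.linalg.norm(C.centroid[0] - A.centroid[-1])
        dB = np.linalg.norm(C.centroid[0] - B.centroid[-1])
        assert dA < dB


class TestJoinFragments:
    def _gap_pair(self, gap_px, gap_s, px_per_mm=4.0):
        gap_mm = gap_px / px_per_mm
        t1 = np.arange(0, 301) / 10.0
        x1 = np.column_stack([np.linspace(10, 40, 301), np.full(301, 80.0)])
        start2 = int(round((30.0 + gap_s) * 10))
        t2 = np.arange(start2, start2 + 300) / 10.0
        x2 = np.column_stack([np.linspace(40 + gap_mm, 70 + gap_mm, 300),
                              np.full(300, 80.0)])
        return [_track_from_points(0, t1, x1), _track_from_points(1, t2, x2)]

    @pytest.mark.parametrize("gap_px,gap_s,round_joined", [
        (100, 10.0, 1),    # within all round-1 limits (10 px/s)
        (300, 50.0, 2),    # distance and time exceed round 1
        (100, 5.0, 2),     # 20 px/s violates the round-1 speed limit
    ])
    def test_staged_round_membership(self, gap_px, gap_s, round_joined):
        joined = tm.join_fragments(self._gap_pair(gap_px, gap_s))
        assert len(joined) == 1
        assert joined[0].join_rounds == [(round_joined, 1)]
        # and the first round alone joins iff round_joined == 1
        only_r1 = tm.join_fragments(self._gap_pair(gap_px, gap_s),
                                    rounds=tm.FRAGMENT_ROUNDS[:1])
        assert len(only_r1) == (1 if round_joined == 1 else 2)

    def test_no_time_overlap_after_joining(self):
        rng = np.random.default_rng(5)
        pieces = []
        t0 = 0
        for tid in range(6):
            n = int(rng.integers(100, 200))
            t = np.arange(t0, t0 + n) / 10.0
            pts = np.cumsum(rng.normal(0, 0.1, (n, 2)), axis=0) + 80
            pieces.append(_track_from_points(tid, t, pts))
            t0 += n + int(rng.integers(5, 50))
        joined = tm.join_fragments(pieces)
        for tr in joined:
            assert np.all(np.diff(tr.t) > 0)


class TestAssignTemperature:
    def _series(self, values, t=(0.0, 20.0, 40.0)):
        frames = np.stack([np.full((4, 4), v, dtype=float) for v in values])
        return ThermalFrameSeries(frames=frames, timestamps=np.array(t))

    def test_nearest_in_time(self, make_straight_track):
        tr = make_straight_track(duration_s=3.0, start=(80, 80))
        tr.t = tr.t + 29.0  # all samples near t=29: frame at 20 is closer
        series = self._series([10.0, 20.0, 30.0])
        out = tm.assign_temperature(tr, series)
        assert np.all(out.temp_C[tr.t < 30.0] == 20.0)

    def test_tie_goes_to_earlier_frame(self):
        tr = _track_from_points(0, [10.0], [(80.0, 80.0)])
        out = tm.assign_temperature(tr, self._series([10.0, 20.0, 30.0]))
        assert out.temp_C[0] == 10.0  # exactly between frames 0 and 20

    def test_uniform_frames_give_constant(self, make_straight_track):
        tr = make_straight_track(duration_s=10.0, start=(50, 50))
        out = tm.assign_temperature(tr, self._series([21.0, 21.0, 21.0]))
        assert np.all(out.temp_C == 21.0)

    def test_outside_positions_clamped_and_flagged(self):
        tr = _track_from_points(0, [0.0, 0.1], [(-5.0, 50.0), (50.0, 50.0)],
                                head_offset=(0.0, 0.0))
        out = tm.assign_temperature(tr, self._series([21.0, 21.0, 21.0]))
        assert out.temp_flags[0] and not out.temp_flags[1]
        assert out.temp_C[0] == 21.0
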