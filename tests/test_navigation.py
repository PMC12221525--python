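"""Windowed velocity/tortuosity, head-sweep detection, zone statistics."""

import numpy as np
import pytest
from scipy import stats

from larvathermo import navigation as nav
from larvathermo.tracks import Track

from conftest import straight_track


def _track_from_xy(x, y, rate=10.0):
    pts = np.column_stack([x, y])
    t = np.arange(len(x)) / rate
    return Track(id=0, t=t, centroid=pts, head=pts + [2.0, 0.0],
                 bend_deg=np.zeros(len(x)))


class TestWindowedVelocity:
    def test_straight_line_constant_speed(self):
        tr = straight_track(speed_mm_s=1.0, duration_s=30.0)
        v, v_bl, partial = nav.windowed_velocity(tr)
        assert np.allclose(v, 1.0)
        assert np.allclose(v_bl[~partial], 0.25)  # body length 2*2 mm head offset
        assert not partial[len(v) // 2] and partial[0]

    def test_stationary_is_zero(self):
        n = 100
        tr = _track_from_xy(np.full(n, 50.0), np.full(n, 50.0))
        v, _, _ = nav.windowed_velocity(tr)
        assert np.allclose(v, 0.0)

    def test_sawtooth_matches_hand_computed_path(self):
        # vertices every 1 s alternating +-1 mm in y while advancing 1 mm in x:
        # segment length sqrt(2) per 10 frames -> speed sqrt(2)/1 s everywhere
        n = 401
        t = np.arange(n) / 10.0
        x = t.copy()
        y = np.abs((t % 2.0) - 1.0)  # triangle wave, slope +-1 mm/s
        tr = _track_from_xy(x, y)
        v, _, partial = nav.windowed_velocity(tr)
        assert np.allclose(v[~partial], np.sqrt(2.0), rtol=1e-6)

    def test_too_short_track_yields_empty(self):
        tr = straight_track(duration_s=2.0)
        v, v_bl, partial = nav.windowed_velocity(tr, window_s=3.0)
        assert v.size == 0

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(2)
        steps = rng.normal(0, 0.3, (200, 2))
        xy = np.cumsum(steps, axis=0) + 80
        tr = _track_from_xy(xy[:, 0], xy[:, 1])
        ang = 0.7
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        xy2 = xy @ R.T + [5.0, -3.0]
        tr2 = _track_from_xy(xy2[:, 0], xy2[:, 1])
        v1, _, _ = nav.windowed_velocity(tr)
        v2, _, _ = nav.windowed_velocity(tr2)
        assert np.allclose(v1, v2)
        assert np.allclose(nav.windowed_tortuosity(tr),
                           nav.windowed_tortuosity(tr2), equal_nan=True)


class TestWindowedTortuosity:
    def test_straight_path_is_zero(self):
        tr = straight_track(duration_s=60.0)
        tort = nav.windowed_tortuosity(tr)
        assert np.allclose(tort, 0.0, atol=1e-12)

    def test_semicircle_in_one_window(self):
        # semicircle of radius r traversed in exactly 2 s: chord 2r, arc pi*r
        r = 5.0
        n = 21  # 2 s at 10 Hz
        phi = np.linspace(0, np.pi, n)
        tr = _track_from_xy(80 + r * np.cos(phi), 80 + r * np.sin(phi))
        tort = nav.windowed_tortuosity(tr, windows_s=(2.0,))
        centre = n // 2
        assert tort[centre] == pytest.approx(1.0 - 2.0 / np.pi, abs=2e-3)

    def test_closed_loops_score_one(self):
        # revisit the start exactly at every window's endpoints
        n = 601
        t = np.arange(n) / 10.0
        phi = 2 * np.pi * t / 1.0  # full circle per second
        tr = _track_from_xy(80 + np.cos(phi), 80 + np.sin(phi))
        tort = nav.windowed_tortuosity(tr, windows_s=(2.0, 5.0, 10.0))
        interior = slice(160, 440)
        assert np.allclose(tort[interior], 1.0, atol=1e-6)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(4)
        xy = np.cumsum(rng.normal(0, 0.5, (400, 2)), axis=0) + 80
        tort = nav.windowed_tortuosity(_track_from_xy(xy[:, 0], xy[:, 1]))
        valid = tort[np.isfinite(tort)]
        assert np.all((valid >= 0) & (valid <= 1))


class TestHeadSweeps:
    def _bend(self, peaks, peak_spacing_s=10.0, width_s=1.0, rate=10.0,
              rest=5.0):
        """|bend| series with triangular excursions to given peak angles."""
        n = int(peak_spacing_s * rate * (len(peaks) + 1))
        bend = np.full(n, rest)
        w = int(width_s * rate)
        bump = np.concatenate([np.linspace(0, 1, w // 2 + 1)[1:],
                               np.linspace(1, 0, w // 2 + 1)[1:]])
        for k, pk in enumerate(peaks):
            c = int((k + 1) * peak_spacing_s * rate)
            bend[c - w // 2:c + w // 2] = np.maximum(
                bend[c - w // 2:c + w // 2], pk * bump)
        return bend

    def test_single_excursion_accepted(self):
        sweeps = nav.detect_head_sweeps(self._bend([50.0]))
        assert len(sweeps) == 1 and sweeps[0].accepted
        assert sweeps[0].peak_deg == pytest.approx(50.0)

    def test_subthreshold_peak_detected_not_accepted(self):
        sweeps = nav.detect_head_sweeps(self._bend([40.0]))
        assert len(sweeps) == 1 and not sweeps[0].accepted

    def test_peaks_within_buffer_merge_keeping_larger(self):
        bend = np.full(100, 5.0)
        for c, pk in [(30, 50.0), (40, 55.0)]:  # 1 s apart
            bend[c - 3:c + 4] = np.maximum(bend[c - 3:c + 4],
                                           pk * np.array([.3, .6, .9, 1, .9, .6, .3]))
        sweeps = nav.detect_head_sweeps(bend)
        assert len(sweeps) == 1
        assert sweeps[0].peak_deg == pytest.approx(55.0)

    def test_no_return_to_straight_rejected(self):
        bend = np.concatenate([np.full(20, 5.0), np.linspace(5, 60, 30),
                               np.full(50, 25.0)])  # never returns below 10
        assert nav.detect_head_sweeps(bend) == []

    @pytest.mark.parametrize("k", [0, 1, 4, 9])
    def test_planted_count_recovered_exactly(self, k):
        bend = self._bend([50.0 + 3 * i for i in range(k)])
        accepted = [s for s in nav.detect_head_sweeps(bend) if s.accepted]
        assert len(accepted) == k


class TestZoneStatistics:
    def test_zone_of_boundaries(self):
        z = nav.zone_of([17.0, 19.5, 19.67, 22.33, 25.0, 16.0, 26.0])
        assert list(z) == ["cool", "cool", "mid", "warm", "warm", "", ""]

    def test_identical_zones_mean_near_zero(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(1.0, 0.5, 500)
        res = nav.zone_differences({"cool": vals, "mid": vals, "warm": vals},
                                   n_draws=2000, seed=1)
        for c in res.values():
            se = np.std(c["diffs"]) / np.sqrt(len(c["diffs"]))
            assert abs(c["mean"]) < 3 * se + 1e-12

    def test_point_mass_shift_recovered_exactly(self):
        base = np.array([1.0])
        res = nav.zone_differences({"cool": base, "mid": base + 0.3,
                                    "warm": base + 0.8}, n_draws=100, seed=2)
        assert res["warm-cool"]["mean"] == pytest.approx(0.8)
        assert res["mid-cool"]["mean"] == pytest.approx(0.3)
        assert res["warm-mid"]["mean"] == pytest.approx(0.5)

    def test_contrast_linearity_in_expectation(self):
        rng = np.random.default_rng(7)
        zones = {"cool": rng.normal(0, 1, 400), "mid": rng.normal(0.5, 1, 400),
                 "warm": rng.normal(1.2, 1, 400)}
        res = nav.zone_differences(zones, n_draws=20000, seed=3)
        lhs = res["warm-cool"]["mean"]
        rhs = res["warm-mid"]["mean"] + res["mid-cool"]["mean"]
        assert lhs == pytest.approx(rhs, abs=0.05)

    def test_empty_zone_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="empty zone"):
            res = nav.zone_differences({"cool": [1.0], "mid": [],
                                        "warm": [2.0]}, n_draws=10, seed=0)
        assert set(res) == {"warm-cool"}


class TestTrendsAndCorrelation:
    def test_exact_linear_relation(self):
        T = np.linspace(17, 25, 50)
        res = nav.fit_temperature_trend(T, 2.0 * T)
        g = res[0]
        assert g["slope"] == pytest.approx(2.0)
        assert g["r_squared"] == pytest.approx(1.0)

    def test_slope_equals_cov_over_var(self):
        rng = np.random.default_rng(8)
        T = rng.uniform(17, 25, 300)
        y = 0.4 * T + rng.normal(0, 1, 300)
        slope = nav.fit_temperature_trend(T, y)[0]["slope"]
        oracle = np.cov(T, y, bias=True)[0, 1] / np.var(T)
        assert slope == pytest.approx(oracle, rel=1e-10)

    def test_pure_noise_ci_contains_zero(self):
        rng = np.random.default_rng(9)
        T = rng.uniform(17, 25, 1000)
        y = rng.normal(0, 1, 1000)
        lo, hi = nav.fit_temperature_trend(T, y)[0]["slope_ci"]
        assert lo < 0 < hi

    def test_constant_temperature_raises(self):
        with pytest.raises(ValueError, match="constant temperature"):
            nav.fit_temperature_trend(np.full(10, 21.0), np.arange(10.0))

    def test_perfect_anticorrelation(self):
        v = np.linspace(0.1, 1.0, 50)
        r, _ = nav.correlate(v, -v)
        assert r == pytest.approx(-1.0)

    def test_independent_noise_has_small_r(self):
        rng = np.random.default_rng(10)
        r, _ = nav.correlate(rng.normal(size=10_000), rng.normal(size=10_000))
        assert abs(r) < 0.05

    def test_clade_compare_detects_shift(self):
        rng = np.random.default_rng(11)
        a = {z: rng.normal(0, 1, 100) for z in nav.ZONES}
        b = {z: rng.normal(2, 1, 100) for z in nav.ZONES}
        res = nav.clade_compare(a, b)
        assert all(p < 0.001 for p in res["p_adjusted"])
        same = nav.clade_compare(a, a)
        assert all(p > 0.9 for p in same["p_raw"])
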