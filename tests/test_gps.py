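"""GPS mobility: distances, movement annotation, clustering, home, features."""

import numpy as np
import pandas as pd
import pytest

from affectsense import gps, synthetic
from conftest import make_gps_frame, offset_latlon
from oracles import brute_force_dbscan, law_of_cosines_m, partitions_equal

ALEX = (52.521992, 13.413244)


class TestHaversine:
    def test_identity(self):
        assert gps.haversine_m(ALEX, ALEX) == 0.0

    def test_antipodal_on_equator(self):
        assert gps.haversine_m((0, 0), (0, 180)) == pytest.approx(np.pi * gps.EARTH_RADIUS_M)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform([-80, -180], [80, 180])
            q = p + rng.normal(0, 0.5, 2)
            d1 = gps.haversine_m(p, q)
            assert d1 == gps.haversine_m(q, p) and d1 >= 0

    def test_against_law_of_cosines(self):
        p = (52.5220, 13.4132)
        q = (52.5230, 13.4132)
        expected = law_of_cosines_m(*p, *q)
        assert gps.haversine_m(p, q) == pytest.approx(expected, rel=1e-3)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            pts = rng.uniform([-80, -180], [80, 180], size=(3, 2))
            d = [gps.haversine_m(pts[i], pts[j])
                 for i, j in ((0, 1), (1, 2), (0, 2))]
            assert d[2] <= d[0] + d[1] + 1e-6


class TestAnnotateMovement:
    def _two_points(self, dist_m, dt_s):
        p0 = ALEX
        p1 = offset_latlon(*p0, dist_m, 0)
        t0 = pd.Timestamp("2023-05-01 10:00", tz="UTC")
        return make_gps_frame([p0, p1], [t0, t0 + pd.Timedelta(seconds=dt_s)])

    def test_slow_and_near_is_stationary(self):
        ann = gps.annotate_movement(self._two_points(100, 100))  # 1 m/s
        assert bool(ann["stationary"].iloc[1])
        assert ann["speed_mps"].iloc[1] == pytest.approx(1.0, rel=0.01)

    def test_at_walking_speed_is_transition(self):
        # distance/dt chosen so speed lands at/above 1.4 m/s
        df = self._two_points(140, 99)
        ann = gps.annotate_movement(df)
        assert ann["speed_mps"].iloc[1] >= 1.4
        assert not bool(ann["stationary"].iloc[1])

    def test_slow_but_far_is_transition(self):
        ann = gps.annotate_movement(self._two_points(200, 400))  # 0.5 m/s, 200 m
        assert not bool(ann["stationary"].iloc[1])

    def test_first_point_inherits_first_pair(self):
        ann = gps.annotate_movement(self._two_points(100, 100))
        assert bool(ann["stationary"].iloc[0])

    def test_duplicate_timestamp_flagged_degenerate(self):
        df = self._two_points(100, 0)
        ann = gps.annotate_movement(df)
        assert bool(ann["degenerate"].iloc[1])
        assert np.isnan(ann["speed_mps"].iloc[1])

    def test_dwell_capped(self):
        p0 = ALEX
        t0 = pd.Timestamp("2023-05-01 10:00", tz="UTC")
        df = make_gps_frame([p0, p0, p0],
                            [t0, t0 + pd.Timedelta(hours=2), t0 + pd.Timedelta(hours=2, minutes=5)])
        ann = gps.annotate_movement(df)
        assert ann["dwell_min"].iloc[0] == gps.DWELL_CAP_MIN
        assert ann["dwell_min"].iloc[1] == pytest.approx(5.0)
        assert ann["dwell_min"].iloc[2] == 0.0


def _blob(rng, center, n, spread_m, t0, step_min=10.0):
    pts, times = [], []
    for i in range(n):
        pts.append(offset_latlon(*center, rng.normal(0, spread_m), rng.normal(0, spread_m)))
        times.append(t0 + pd.Timedelta(minutes=i * step_min))
    return pts, times


def _stationary_frame(df):
    ann = gps.annotate_movement(df)
    return ann[ann["stationary"]].reset_index(drop=True)


class TestClusterStationary:
    def test_single_dense_blob_is_one_cluster(self):
        rng = np.random.default_rng(0)
        t0 = pd.Timestamp("2023-05-01", tz="UTC")
        pts, times = _blob(rng, ALEX, 100, 8, t0)
        stat = _stationary_frame(make_gps_frame(pts, times))
        cs = gps.cluster_stationary(stat, n_total_points=100)
        assert cs.n_clusters == 1
        assert (cs.assignments == 0).all()

    def test_two_far_blobs_two_clusters(self):
        rng = np.random.default_rng(1)
        t0 = pd.Timestamp("2023-05-01", tz="UTC")
        far = offset_latlon(*ALEX, 1000, 0)
        p1, t1 = _blob(rng, ALEX, 40, 8, t0)
        p2, t2 = _blob(rng, far, 40, 8, t0 + pd.Timedelta(days=1))
        stat = _stationary_frame(make_gps_frame(p1 + p2, t1 + t2))
        cs = gps.cluster_stationary(stat, n_total_points=80)
        assert cs.n_clusters == 2

    def test_min_samples_rule(self):
        assert gps.min_samples_for(100) == 3
        assert gps.min_samples_for(50) == 2
        assert gps.min_samples_for(10) == 2  # floored at 2

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        t0 = pd.Timestamp("2023-05-01", tz="UTC")
        far = offset_latlon(*ALEX, 600, 300)
        p1, t1 = _blob(rng, ALEX, 30, 20, t0)
        p2, t2 = _blob(rng, far, 25, 20, t0 + pd.Timedelta(hours=12))
        stat = _stationary_frame(make_gps_frame(p1 + p2, t1 + t2))
        cs0 = gps.cluster_stationary(stat, n_total_points=60)
        perm = rng.permutation(len(stat))
        cs1 = gps.cluster_stationary(stat.iloc[perm].reset_index(drop=True), n_total_points=60)
        # map permuted labels back to the original row order
        restored = np.empty(len(stat), int)
        restored[perm] = cs1.assignments
        assert partitions_equal(cs0.assignments, restored)

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        t0 = pd.Timestamp("2023-05-01", tz="UTC")
        for trial in range(5):
            centers = [offset_latlon(*ALEX, *rng.uniform(-400, 400, 2)) for _ in range(3)]
            pts, times = [], []
            k = 0
            for c in centers:
                p, t = _blob(rng, c, int(rng.integers(10, 40)), 30,
                             t0 + pd.Timedelta(hours=k))
                pts += p
                times += t
                k += 24
            stat = make_gps_frame(pts, times).sort_values("timestamp").reset_index(drop=True)
            stat["dwell_min"] = 1.0
            n_total = len(stat)
            cs = gps.cluster_stationary(stat, n_total_points=n_total)
            coords = np.radians(stat[["lat", "lon"]].to_numpy())
            key = stat["timestamp"].dt.tz_localize(None).to_numpy().astype(np.int64)
            labels, core = brute_force_dbscan(coords, cs.eps_used, cs.min_samples_used,
                                              order_key=key)
            assert (core == cs.core_mask).all()
            assert partitions_equal(cs.assignments, labels)


class TestFindHome:
    def _night_trace(self, n_nights_a, n_nights_b, n_total=200):
        """Stationary points: cluster A occupied on some nights, B on others."""
        rng = np.random.default_rng(4)
        locA = ALEX
        locB = offset_latlon(*ALEX, 2000, 0)
        pts, times = [], []
        start = pd.Timestamp("2023-05-01", tz="UTC")
        for night in range(14):
            loc = locA if night < n_nights_a else (locB if night < n_nights_a + n_nights_b else None)
            if loc is None:
                continue
            t0 = start + pd.Timedelta(days=night, hours=21)
            for i in range(6):
                pts.append(offset_latlon(*loc, rng.normal(0, 10), rng.normal(0, 10)))
                times.append(t0 + pd.Timedelta(minutes=40 * i))
        df = make_gps_frame(pts, times)
        ann = gps.annotate_movement(df)
        stat = ann[ann["stationary"]].reset_index(drop=True)
        cs = gps.cluster_stationary(stat, n_total_points=n_total)
        nights = gps.night_windows(df["timestamp"].min(), df["timestamp"].max())
        return gps.find_home(cs, stat, nights), stat

    def test_dominant_cluster_is_home(self):
        cs, _ = self._night_trace(10, 4)
        assert cs.home_id is not None and not cs.home_is_fallback
        assert cs.night_counts[cs.home_id] >= 4

    def test_no_qualifier_falls_back_to_most_visited(self):
        cs, stat = self._night_trace(3, 3)
        assert cs.home_is_fallback
        assert cs.home_id is not None

    def test_empty_clusters_no_home(self):
        empty = pd.DataFrame(columns=["timestamp", "lat", "lon", "dwell_min"])
        cs = gps.cluster_stationary(empty, n_total_points=100)
        cs = gps.find_home(cs, empty, [])
        assert cs.home_id is None


class TestEndToEndHomeDetection:
    def test_homebody_home_detected_near_planted_location(self):
        rng = np.random.default_rng(6)
        home = ALEX
        parts = []
        d0 = pd.Timestamp("2023-05-01", tz="UTC")
        for day in range(14):
            parts.append(synthetic.generate_gps_trace(
                rng, d0 + pd.Timedelta(days=day), d0 + pd.Timedelta(days=day + 1),
                home, legs=[]))
        trace = pd.concat(parts, ignore_index=True)
        # no excursions: every point within 100 m of home
        d = gps.haversine_m((trace["lat"].to_numpy(), trace["lon"].to_numpy()),
                            (np.full(len(trace), home[0]), np.full(len(trace), home[1])))
        assert np.max(d) < 100
        res = gps.process_trace(trace)
        assert res.cluster_set.home_id is not None
        stat = res.annotated[res.annotated["stationary"]].reset_index(drop=True)
        members = res.cluster_set.assignments == res.cluster_set.home_id
        centroid = (stat.loc[members, "lat"].mean(), stat.loc[members, "lon"].mean())
        assert gps.haversine_m(centroid, home) < 100

    def test_excursion_speed_recovered_from_trace(self):
        rng = np.random.default_rng(8)
        home = ALEX
        away = offset_latlon(*ALEX, 3000, 0)
        d0 = pd.Timestamp("2023-05-01", tz="UTC")
        t0 = d0 + pd.Timedelta(hours=10)
        t1 = t0 + pd.Timedelta(minutes=10)
        trace = synthetic.generate_gps_trace(rng, d0, d0 + pd.Timedelta(days=1),
                                             home, [(t0, t1, home, away, 5.0)])
        ann = gps.annotate_movement(trace)
        moving = ann[(ann["timestamp"] > t0 - pd.Timedelta(hours=1)) &
                     (ann["timestamp"] <= t1 - pd.Timedelta(hours=1)) &
                     ~ann["stationary"]]
        speeds = moving["speed_mps"].dropna()
        assert len(speeds) > 5
        assert np.median(speeds) == pytest.approx(5.0, rel=0.2)


class TestClusterReport:
    def test_report_is_json_ready_and_flags_home(self, small_cohort):
        import json
        res = gps.process_trace(small_cohort.streams["p001"]["gps"])
        rep = gps.cluster_report(res)
        json.dumps(rep)  # serializable
        assert rep["n_points_total"] == len(res.annotated)
        homes = [c for c in rep["clusters"] if c["is_home"]]
        if rep["home_id"] is not None:
            assert len(homes) == 1 and homes[0]["id"] == rep["home_id"]
        assert all(c["n_points"] >= 1 for c in rep["clusters"])


class TestMobilityFeatures:
    def test_empty_window_marks_missing(self):
        df = make_gps_frame([ALEX], [pd.Timestamp("2023-05-01 08:00", tz="UTC")])
        ann = gps.annotate_movement(df)
        w = (pd.Timestamp("2023-05-02 08:00", tz="UTC"), pd.Timestamp("2023-05-02 10:00", tz="UTC"))
        f = gps.mobility_features(ann, np.array([0]), 0, w)
        assert f["missing_gps"] and np.isnan(f["distance_km"])

    def test_excursion_distance_and_transition_minutes(self):
        rng = np.random.default_rng(12)
        home = ALEX
        away = offset_latlon(*ALEX, 3600, 0)
        d0 = pd.Timestamp("2023-05-01", tz="UTC")
        t0 = d0 + pd.Timedelta(hours=10)
        t1 = t0 + pd.Timedelta(minutes=12)  # 3.6 km at 5 m/s
        trace = synthetic.generate_gps_trace(rng, d0, d0 + pd.Timedelta(days=1),
                                             home, [(t0, t1, home, away, 5.0)])
        res = gps.process_trace(trace)
        w = (t0 - pd.Timedelta(hours=1, minutes=48), t1 - pd.Timedelta(hours=1))
        f = gps.mobility_features(res.annotated, res.labels_full,
                                  res.cluster_set.home_id, w)
        assert f["distance_km"] == pytest.approx(3.6, rel=0.15)
        assert f["minutes_transition"] == pytest.approx(12.0, rel=0.25)

    def test_home_minutes_bounded_by_stationary(self, small_cohort):
        pid = "p000"
        res = gps.process_trace(small_cohort.streams[pid]["gps"])
        t0 = small_cohort.beeps[pid]["timestamp"].iloc[10]
        f = gps.mobility_features(res.annotated, res.labels_full,
                                  res.cluster_set.home_id,
                                  (t0 - pd.Timedelta(hours=2), t0))
        if not f["missing_gps"] and not np.isnan(f["minutes_home"]):
            assert f["minutes_home"] <= f["minutes_stationary"] + 1e-9
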