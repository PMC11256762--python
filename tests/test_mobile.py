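"""Drive-log aggregation: snapping, pass splitting, median-of-means."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

import bcfuse as bf
from bcfuse.mobile import RoadSegment


def _points(rows):
    return pd.DataFrame(
        rows, columns=["timestamp", "vehicle_id", "x", "y", "bc", "no"]
    ).assign(timestamp=lambda d: pd.to_datetime(d["timestamp"]))


SEG_A = RoadSegment("A", LineString([(0, 0), (30, 0)]))
SEG_B = RoadSegment("B", LineString([(0, 20), (30, 20)]))


class TestSnap:
    def test_point_on_midpoint_assigned(self):
        pts = _points([("2017-05-19 09:00:00", "v", 15.0, 0.0, 1.0, 1.0)])
        assert bf.snap_to_segments(pts, [SEG_A, SEG_B]).tolist() == ["A"]

    def test_beyond_max_dist_unassigned(self):
        pts = _points([("2017-05-19 09:00:00", "v", 15.0, 31.0, 1.0, 1.0)])
        out = bf.snap_to_segments(pts, [SEG_A], max_dist=30.0)
        assert out.isna().all()

    def test_equidistant_tie_breaks_lexicographically(self):
        pts = _points([("2017-05-19 09:00:00", "v", 15.0, 10.0, 1.0, 1.0)])
        assert bf.snap_to_segments(pts, [SEG_B, SEG_A]).tolist() == ["A"]

    def test_empty_segment_set_rejected(self):
        with pytest.raises(ValueError):
            bf.snap_to_segments(_points([]), [])


class TestPasses:
    def test_single_pass_mean(self):
        pts = _points(
            [(f"2017-05-19 09:00:0{i}", "v", 1.0 + i, 0.0, v, 2 * v) for i, v in enumerate([1.0, 2.0, 3.0])]
        )
        pts["segment_id"] = "A"
        out = bf.drive_pass_means(pts)
        assert len(out) == 1
        assert out.loc[0, "bc"] == pytest.approx(2.0)
        assert out.loc[0, "no"] == pytest.approx(4.0)

    def test_gap_over_sixty_seconds_splits_pass(self):
        pts = _points(
            [
                ("2017-05-19 09:00:00", "v", 1.0, 0.0, 1.0, 1.0),
                ("2017-05-19 09:02:00", "v", 2.0, 0.0, 3.0, 1.0),
            ]
        )
        pts["segment_id"] = "A"
        assert len(bf.drive_pass_means(pts)) == 2

    def test_vehicle_change_splits_pass(self):
        pts = _points(
            [
                ("2017-05-19 09:00:00", "u", 1.0, 0.0, 1.0, 1.0),
                ("2017-05-19 09:00:01", "w", 2.0, 0.0, 3.0, 1.0),
            ]
        )
        pts["segment_id"] = "A"
        assert len(bf.drive_pass_means(pts)) == 2

    def test_matches_brute_force_groupby_oracle(self):
        rng = np.random.default_rng(10)
        n = 400
        t0 = pd.Timestamp("2017-05-19 09:00:00")
        pts = pd.DataFrame(
            {
                "timestamp": t0 + pd.to_timedelta(np.arange(n), unit="s"),
                "vehicle_id": np.where(rng.random(n) < 0.5, "u", "w"),
                "x": rng.random(n),
                "y": rng.random(n),
                "segment_id": rng.choice(["A", "B", "C"], n),
                "bc": rng.normal(1.0, 0.3, n),
                "no": rng.normal(5.0, 1.0, n),
            }
        )
        out = bf.drive_pass_means(pts)
        # independent oracle: explicit loop building passes point by point
        expected = []
        for veh in sorted(pts["vehicle_id"].unique()):
            sub = pts[pts["vehicle_id"] == veh].sort_values("timestamp")
            cur, prev_t, prev_seg = [], None, None
            for _, row in sub.iterrows():
                boundary = (
                    prev_t is None
                    or (row["timestamp"] - prev_t).total_seconds() > 60
                    or row["segment_id"] != prev_seg
                )
                if boundary and cur:
                    expected.append(cur)
                    cur = []
                cur.append(row)
                prev_t, prev_seg = row["timestamp"], row["segment_id"]
            if cur:
                expected.append(cur)
        assert len(out) == len(expected)
        ours = out.sort_values(["vehicle_id", "start"]).reset_index(drop=True)
        for i, grp in enumerate(
            sorted(expected, key=lambda g: (g[0]["vehicle_id"], g[0]["timestamp"]))
        ):
            assert ours.loc[i, "bc"] == pytest.approx(np.mean([r["bc"] for r in grp]))
            assert ours.loc[i, "n_points"] == len(grp)


def _pass_frame(seg_values: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    t = pd.Timestamp("2017-05-19 09:00:00")
    for seg, vals in seg_values.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "segment_id": seg,
                    "vehicle_id": "v",
                    "start": t + pd.Timedelta(minutes=i),
                    "n_points": 5,
                    "bc": v,
                    "no": 2 * v,
                }
            )
    return pd.DataFrame(rows)


class TestMedianOfMeans:
    def test_even_count_median_is_midpoint(self):
        m = bf.median_of_means(_pass_frame({"A": [2.0, 4.0]}), min_visits=1)
        assert m.values[m.pollutants.index("bc"), 0] == pytest.approx(3.0)

    def test_segment_below_visit_threshold_dropped(self):
        frame = _pass_frame({"A": [1.0] * 14, "B": [1.0] * 15})
        m = bf.median_of_means(frame, min_visits=15)
        assert m.locations == ["B"]

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError, match="visit threshold"):
            bf.median_of_means(_pass_frame({"A": [1.0]}), min_visits=5)

    def test_matches_sort_based_oracle(self):
        rng = np.random.default_rng(11)
        frame = _pass_frame(
            {f"s{i:02d}": rng.normal(2.0, 1.0, rng.integers(3, 30)).tolist() for i in range(50)}
        )
        m = bf.median_of_means(frame, min_visits=3)
        for j, seg in enumerate(m.locations):
            vals = sorted(frame.loc[frame["segment_id"] == seg, "bc"])
            n = len(vals)
            med = vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            assert m.values[0, j] == pytest.approx(max(med, 0.0))

    def test_invariant_to_pass_order(self):
        rng = np.random.default_rng(12)
        frame = _pass_frame({"A": rng.random(9).tolist(), "B": rng.random(7).tolist()})
        m1 = bf.median_of_means(frame, min_visits=1)
        m2 = bf.median_of_means(frame.sample(frac=1.0, random_state=5), min_visits=1)
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_homogeneous_in_concentration_scale(self):
        frame = _pass_frame({"A": [1.0, 2.0, 5.0], "B": [0.5, 0.7]})
        doubled = frame.copy()
        doubled[["bc", "no"]] *= 2.0
        m1 = bf.median_of_means(frame, min_visits=1)
        m2 = bf.median_of_means(doubled, min_visits=1)
        np.testing.assert_allclose(m2.values, 2.0 * m1.values)

    def test_negative_medians_clipped_and_counted(self):
        frame = _pass_frame({"A": [-1.0, -2.0, -0.5]})
        m = bf.median_of_means(frame, min_visits=1)
        assert (m.values >= 0).all()
        assert m.n_clipped == 2  # bc and no medians both negative

    def test_no_missing_cells_and_counts_recorded(self, segment_map):
        assert np.isfinite(segment_map.values).all()
        assert (segment_map.visit_counts >= 15).all()
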