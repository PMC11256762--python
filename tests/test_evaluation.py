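"""Metrics, Lagrangian comparisons, cross-validation and sensitivity drivers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcfuse import evaluation as ev
from bcfuse.fusion import BCField


class TestMetrics:
    def test_identity_prediction(self):
        rep = ev.metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.nmb == rep.nmae == rep.nrmse == 0.0

    def test_constant_offset(self):
        rep = ev.metrics([1.0] * 4, [2.0] * 4)
        assert rep.nmb == pytest.approx(1.0)
        assert rep.nmae == pytest.approx(1.0)
        assert rep.nrmse == pytest.approx(1.0)
        assert np.isnan(rep.pearson_r)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.random(100) + 0.5, rng.random(100) + 0.5
        rep = ev.metrics(obs, pred)
        assert rep.nmb == pytest.approx((pred - obs).sum() / obs.sum())
        assert rep.nmae == pytest.approx(np.abs(pred - obs).sum() / obs.sum())
        assert rep.nrmse == pytest.approx(np.sqrt(np.mean((pred - obs) ** 2)) / obs.mean())
        ox, px = obs - obs.mean(), pred - pred.mean()
        assert rep.pearson_r == pytest.approx(
            (ox * px).sum() / np.sqrt((ox**2).sum() * (px**2).sum())
        )

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ev.metrics([1.0], [1.0])

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
    def test_scale_equivariance(self, seed, scale):
        # normalized metrics are invariant to a common rescaling of both series
        rng = np.random.default_rng(seed)
        obs, pred = rng.random(30) + 0.1, rng.random(30) + 0.1
        a, b = ev.metrics(obs, pred), ev.metrics(scale * obs, scale * pred)
        assert a.nmb == pytest.approx(b.nmb)
        assert a.nmae == pytest.approx(b.nmae)
        assert a.nrmse == pytest.approx(b.nrmse)


def _field(values, locations, start="2017-05-19", n=None):
    values = np.asarray(values, dtype=float)
    return BCField(
        values=values,
        location_order=locations,
        time_bins=pd.date_range(start, periods=values.shape[1], freq="15min"),
    )


def _window_points(bins_to_segs, bc=1.0, start="2017-05-19 00:00:00"):
    """Points for given 15-min bins: {bin: [(segment, n_points), ...]}."""
    rows = []
    t0 = pd.Timestamp(start)
    for b, segs in bins_to_segs.items():
        i = 0
        for seg, n in segs:
            for _ in range(n):
                rows.append(
                    {"timestamp": t0 + pd.Timedelta(seconds=900 * b + i), "vehicle_id": "v",
                     "x": 0.0, "y": 0.0, "segment_id": seg,
                     "bc": bc if np.isscalar(bc) else bc[seg]}
                )
                i += 1
    return pd.DataFrame(rows)


class TestLagrangian:
    def test_single_segment_window_takes_that_value(self):
        field = _field(np.full((1, 96), 7.0), ["A"])
        pts = _window_points({0: [("A", 400)], 1: [("A", 400)]}, bc=6.5)
        table, rep = ev.lagrangian_compare(pts, field, min_points=300)
        assert len(table) == 2
        assert table["predicted_mean"].tolist() == pytest.approx([7.0, 7.0])
        assert table["measured_mean"].tolist() == pytest.approx([6.5, 6.5])

    def test_two_segment_window_averages_each_once(self):
        vals = np.vstack([np.full(96, 2.0), np.full(96, 4.0)])
        field = _field(vals, ["A", "B"])
        # B visited twice as long: distinct segments still count once each
        pts = _window_points({0: [("A", 200), ("B", 400)], 1: [("A", 300), ("B", 300)]})
        table, _ = ev.lagrangian_compare(pts, field, min_points=300)
        assert table["predicted_mean"].tolist() == pytest.approx([3.0, 3.0])

    def test_thin_windows_dropped(self):
        field = _field(np.full((1, 96), 1.0), ["A"])
        pts = _window_points({0: [("A", 100)], 1: [("A", 100)]})
        with pytest.raises(ValueError, match="min_points"):
            ev.lagrangian_compare(pts, field, min_points=300)

    def test_self_consistent_scene_has_high_r(self, scene, drive):
        # use the truth itself as the "model": r limited only by sampling noise
        field = BCField(
            values=scene.bc_truth,
            location_order=scene.location_ids,
            time_bins=scene.time_bins,
        )
        _, rep = ev.lagrangian_compare(drive, field)
        assert rep.pearson_r > 0.97
        assert abs(rep.nmb) < 0.02


class TestCampaignSpatial:
    def test_time_constant_field_returns_static_value(self):
        vals = np.vstack([np.full(96, 3.3), np.full(96, 1.1)])
        field = _field(vals, ["A", "B"])
        pts = _window_points({0: [("A", 450), ("B", 450)], 4: [("A", 450), ("B", 450)]}, bc=3.0)
        table, _ = ev.campaign_spatial_compare(pts, field, min_visits=1)
        got = table.set_index("segment_id")["predicted_median"]
        assert got["A"] == pytest.approx(3.3)
        assert got["B"] == pytest.approx(1.1)

    def test_median_over_pass_bins(self):
        vals = np.zeros((2, 96))
        vals[0, [36, 40, 44]] = [1.0, 5.0, 3.0]
        vals[1] = 2.0
        field = _field(vals, ["A", "B"])
        rows = []
        for b in (36, 40, 44):
            t0 = pd.Timestamp("2017-05-19") + pd.Timedelta(minutes=15 * b)
            for seg in ("A", "B"):
                for i in range(3):
                    rows.append({"timestamp": t0 + pd.Timedelta(seconds=i + (0 if seg == "A" else 60)),
                                 "vehicle_id": "v", "x": 0, "y": 0, "segment_id": seg, "bc": 2.0})
        table, _ = ev.campaign_spatial_compare(pd.DataFrame(rows), field, min_visits=1)
        got = table.set_index("segment_id")["predicted_median"]
        assert got["A"] == pytest.approx(3.0)  # median of field values 1, 5, 3


class TestLeaveSitesOut:
    def test_identical_seed_reproduces_exactly(self, segment_map, sensor_matrix, scene):
        kw = dict(n_iter=3, seed=11, k=5, q=6, nmf_max_iter=200)
        a = ev.leave_sites_out_cv(segment_map, sensor_matrix, scene.sites, **kw)
        b = ev.leave_sites_out_cv(segment_map, sensor_matrix, scene.sites, **kw)
        pd.testing.assert_frame_equal(a.per_site, b.per_site)

    def test_single_site_holdout_boundary(self, segment_map, sensor_matrix, scene):
        res = ev.leave_sites_out_cv(
            segment_map, sensor_matrix, scene.sites,
            holdout_fraction=0.017, n_iter=2, seed=0, k=5, q=6, nmf_max_iter=200,
        )
        assert res.summary["n_holdout"] == 1
        assert np.isfinite(res.per_site["pearson_r"]).all()

    def test_too_few_training_sites_rejected(self, segment_map, sensor_matrix, scene):
        with pytest.raises(ValueError, match="holdout_fraction"):
            ev.leave_sites_out_cv(segment_map, sensor_matrix, scene.sites, holdout_fraction=1.5)


class TestSensitivityDrivers:
    def test_site_count_curve_nondecreasing_within_iqr(self, segment_map, sensor_matrix, scene):
        curve = ev.sensitivity_site_count(
            segment_map, sensor_matrix, scene.sites,
            site_counts=(10, 20, 40, 60), n_iter=8, seed=13, k=5, q=6, nmf_max_iter=200,
        )
        med, q25 = curve["median_r"].to_numpy(), curve["q25_r"].to_numpy()
        iqr = curve["q75_r"].to_numpy() - q25
        # monotone up to one IQR of slack
        assert all(med[i + 1] >= med[i] - iqr[i] for i in range(len(med) - 1))
        # all-sites run should essentially match the full model
        assert med[-1] > 0.9

    def test_sizes_below_k_skipped_with_warning(self, segment_map, sensor_matrix, scene):
        with pytest.warns(UserWarning, match="skipped"):
            curve = ev.sensitivity_site_count(
                segment_map, sensor_matrix, scene.sites,
                site_counts=(3, 20), n_iter=2, seed=0, k=5, q=6, nmf_max_iter=100,
            )
        assert curve["n_sites"].tolist() == [20]

    def test_pollutant_count_runs_down_to_bc_only(self, segment_map, sensor_matrix, scene):
        curve = ev.sensitivity_pollutant_count(
            segment_map, sensor_matrix, scene.sites,
            pollutant_counts=(1, 3, 6), n_iter=3, seed=14, k=5, q=6, nmf_max_iter=200,
        )
        assert curve["n_pollutants"].tolist() == [1, 3, 6]
        assert curve.loc[0, "k_used"] == 1
        assert np.isfinite(curve["median_r"]).all()

    def test_shared_structure_improves_with_pollutants(self, segment_map, sensor_matrix, scene):
        curve = ev.sensitivity_pollutant_count(
            segment_map, sensor_matrix, scene.sites,
            pollutant_counts=(2, 6), n_iter=6, seed=15, k=5, q=6, nmf_max_iter=200,
        )
        iqr = curve["q75_r"] - curve["q25_r"]
        assert curve.loc[1, "median_r"] >= curve.loc[0, "median_r"] - iqr[0]


class TestCarHoldout:
    def test_both_holdouts_close_and_symmetric(self, drive, sensor_matrix, scene):
        coords = {s.segment_id: s.midpoint for s in scene.segments}
        rs = []
        for veh in ("car-a", "car-b"):
            _, rep = ev.car_holdout(
                drive, sensor_matrix, scene.sites, veh,
                segment_coords=coords, k=5, q=6, nmf_max_iter=300,
            )
            rs.append(rep.pearson_r)
        assert abs(rs[0] - rs[1]) < 0.1
        assert min(rs) > 0.7

    def test_missing_vehicle_rejected(self, drive, sensor_matrix, scene):
        with pytest.raises(ValueError, match="ghost"):
            ev.car_holdout(drive, sensor_matrix, scene.sites, "ghost")


class TestTemporalSubsets:
    def test_category_masks_partition_bins(self, scene):
        tb = scene.time_bins
        hours, weekday = tb.hour, tb.dayofweek < 5
        day = (hours >= 9) & (hours < 16)
        sizes = [
            (weekday & day).sum(), (weekday & ~day).sum(),
            (~weekday & day).sum(), (~weekday & ~day).sum(),
        ]
        assert sum(sizes) == len(tb)

    def test_all_weekday_fixture_has_no_weekend_categories(self):
        tb = pd.date_range("2017-05-22", periods=96 * 2, freq="15min")  # Mon-Tue
        rng = np.random.default_rng(5)
        obs = rng.random((3, len(tb)))
        out = ev.temporal_subset_report(obs, obs + 0.01, tb)
        assert set(out) == {"weekday_day", "weekday_night"}

    def test_stationary_noise_gives_uniform_skill(self, scene):
        rng = np.random.default_rng(16)
        obs = scene.bc_truth[len(scene.segments):]
        pred = obs * rng.lognormal(0, 0.05, size=obs.shape)
        out = ev.temporal_subset_report(obs, pred, scene.time_bins)
        rs = [rep.pearson_r for rep in out.values()]
        assert len(out) == 4
        assert max(rs) - min(rs) < 0.05
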