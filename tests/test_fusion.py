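"""Sampling matrix, reprojection, reconstruction, and end-to-end fusion."""

import numpy as np
import pytest

import bcfuse as bf
from bcfuse.fusion import (
    build_sampling_matrix,
    fit_reprojection,
    fuse,
    reconstruct,
)


class TestSamplingMatrix:
    def test_identity_when_sites_equal_locations(self):
        phi = build_sampling_matrix(["a", "b", "c"], ["a", "b", "c"])
        np.testing.assert_array_equal(phi.matrix, np.eye(3))

    def test_unit_rows_at_site_indices(self):
        phi = build_sampling_matrix(["s1", "s3"], ["l0", "s1", "l2", "s3", "l4"])
        expected = np.zeros((2, 5))
        expected[0, 1] = expected[1, 3] = 1.0
        np.testing.assert_array_equal(phi.matrix, expected)

    def test_row_selection_matches_direct_indexing(self):
        rng = np.random.default_rng(0)
        locations = [f"loc{i}" for i in range(25)]
        sites = [locations[i] for i in rng.permutation(25)[:8]]
        phi = build_sampling_matrix(sites, locations)
        X = rng.random((25, 12))
        idx = [locations.index(s) for s in sites]
        np.testing.assert_array_equal(phi.matrix @ X, X[idx])

    def test_unmatched_site_named(self):
        with pytest.raises(ValueError, match="ghost"):
            build_sampling_matrix(["ghost"], ["a", "b"])


class TestReprojection:
    def test_identity_design_returns_ws(self):
        k = 4
        H_L = np.eye(k)  # Φ H_Lᵀ = I when sites = locations and H_L = I
        phi = build_sampling_matrix(list("abcd"), list("abcd"))
        W_S = np.random.default_rng(1).random((k, 6))
        C = fit_reprojection(H_L, phi, W_S).matrix
        np.testing.assert_allclose(C, W_S, atol=1e-12)

    def test_consistent_system_recovers_true_coefficients(self):
        rng = np.random.default_rng(2)
        k, q, s, l = 4, 6, 20, 50
        H_L = rng.random((k, l))
        locations = [f"l{i}" for i in range(l)]
        phi = build_sampling_matrix(locations[:s], locations)
        C_true = rng.random((k, q))
        W_S = (phi.matrix @ H_L.T) @ C_true
        C = fit_reprojection(H_L, phi, W_S).matrix
        np.testing.assert_allclose(C, C_true, atol=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k, q, s = 3, 5, 12
            A = rng.random((s, k)) + 0.1
            W_S = rng.random((s, q)) + 0.1
            H_L = np.zeros((k, s))
            locations = [f"l{i}" for i in range(s)]
            phi = build_sampling_matrix(locations, locations)
            C = fit_reprojection(A.T, phi, W_S).matrix
            C_ne = np.linalg.solve(A.T @ A, A.T @ W_S)
            np.testing.assert_allclose(C, C_ne, atol=1e-8)

    def test_zero_ws_column_rejected(self):
        H_L = np.random.default_rng(4).random((2, 5))
        phi = build_sampling_matrix([f"l{i}" for i in range(4)], [f"l{i}" for i in range(5)])
        W_S = np.ones((4, 3))
        W_S[:, 1] = 0.0
        with pytest.raises(ValueError, match="zero"):
            fit_reprojection(H_L, phi, W_S)

    def test_underdetermined_warns(self):
        rng = np.random.default_rng(5)
        H_L = rng.random((5, 8))
        phi = build_sampling_matrix(["l0", "l1", "l2"], [f"l{i}" for i in range(8)])
        with pytest.warns(UserWarning, match="underdetermined"):
            fit_reprojection(H_L, phi, rng.random((3, 2)) + 0.1)


class TestReconstruct:
    def test_scalar_chain(self):
        field = reconstruct(np.array([[1.0, 1.0]]), np.array([[2.0]]), np.array([[3.0, 4.0]]))
        np.testing.assert_allclose(field.values, [[6.0, 8.0], [6.0, 8.0]])

    def test_rescaling_h_l_cancels_through_pseudoinverse(self):
        rng = np.random.default_rng(6)
        k, q, s, l, t = 4, 6, 25, 60, 30
        H_L = rng.random((k, l)) + 0.1
        H_T = rng.random((q, t))
        locations = [f"l{i}" for i in range(l)]
        phi = build_sampling_matrix(locations[:s], locations)
        W_S = rng.random((s, q)) + 0.1
        base = reconstruct(H_L, fit_reprojection(H_L, phi, W_S), H_T)
        D = np.diag(rng.uniform(0.5, 2.0, k))
        H_L2 = D @ H_L
        scaled = reconstruct(H_L2, fit_reprojection(H_L2, phi, W_S), H_T)
        np.testing.assert_allclose(
            scaled.values, base.values, atol=1e-8 * np.abs(base.values).max()
        )

    def test_site_rows_match_ws_ht_under_exact_fit(self):
        rng = np.random.default_rng(7)
        k, q, s, l, t = 4, 3, 20, 40, 25
        H_L = rng.random((k, l)) + 0.1
        locations = [f"l{i}" for i in range(l)]
        phi = build_sampling_matrix(locations[:s], locations)
        C_true = rng.random((k, q))
        W_S = (phi.matrix @ H_L.T) @ C_true  # consistent system: reprojection residual is zero
        H_T = rng.random((q, t))
        coeff = fit_reprojection(H_L, phi, W_S)
        field = reconstruct(H_L, coeff, H_T)
        np.testing.assert_allclose(phi.matrix @ field.values, W_S @ H_T, atol=1e-8)

    def test_site_error_bounded_by_residual(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            k, q, s, l, t = 3, 5, 15, 30, 20
            H_L = rng.random((k, l)) + 0.1
            locations = [f"l{i}" for i in range(l)]
            phi = build_sampling_matrix(locations[:s], locations)
            W_S = rng.random((s, q)) + 0.1
            H_T = rng.random((q, t))
            coeff = fit_reprojection(H_L, phi, W_S)
            raw = (H_L.T @ coeff.matrix) @ H_T  # before clipping
            gap = np.linalg.norm(phi.matrix @ raw - W_S @ H_T)
            assert gap <= coeff.residual_norm * np.linalg.norm(H_T, 2) + 1e-9

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruct(np.ones((2, 4)), np.ones((3, 3)), np.ones((3, 5)))


class TestFuse:
    def test_oracle_factors_reproduce_truth_exactly(self, scene, truth_map, noiseless_sensor):
        model = fuse(truth_map, noiseless_sensor, oracle_factors=scene.true_factors())
        err = np.linalg.norm(model.bc_field.values - scene.bc_truth) / np.linalg.norm(
            scene.bc_truth
        )
        assert err < 1e-6

    def test_nmf_path_on_noiseless_scene_within_five_percent(
        self, scene, truth_map, noiseless_sensor
    ):
        r = scene.latent_rank
        model = fuse(truth_map, noiseless_sensor, k=r, q=r, nmf_tol=1e-8, nmf_max_iter=3000)
        err = np.linalg.norm(model.bc_field.values - scene.bc_truth) / np.linalg.norm(
            scene.bc_truth
        )
        assert err < 0.05

    def test_flat_source_gives_spatially_constant_field(self):
        cfg = bf.SceneConfig(
            n_sources=1,
            background_level=0.0,
            decay_length_range=(1e7, 1.0000001e7),  # effectively flat over 600 m
            days=2,
            n_sites=20,
        )
        scene = bf.generate_truth(cfg, seed=9)
        truth_map = bf.SegmentConcentrationMap(
            pollutants=scene.pollutants,
            locations=scene.location_ids,
            values=scene.map_truth(),
            visit_counts=np.zeros(len(scene.location_ids), dtype=int),
            coords=scene.location_coords,
        )
        vals = scene.bc_truth[len(scene.segments):]
        sensor = bf.SensorMatrix(
            sites=list(scene.sites["site_id"]),
            time_bins=scene.time_bins,
            bin_width=15,
            values=vals,
            observed_mask=np.ones(vals.shape, dtype=bool),
            imputed_fraction=np.zeros(vals.shape[0]),
        )
        model = fuse(truth_map, sensor, k=1, q=1)
        col = model.bc_field.values
        spread = (col.max(axis=0) - col.min(axis=0)) / col.mean(axis=0)
        assert (spread < 0.01).all()

    def test_dimensional_bookkeeping_at_campaign_scale(self):
        # l = 4370 locations × t = 9600 bins: the full-size field shape
        rng = np.random.default_rng(10)
        l, t, k, q = 4370, 9600, 5, 16
        H_L = rng.random((k, l))
        locations = [f"l{i}" for i in range(l)]
        phi = build_sampling_matrix([f"l{i}" for i in range(4273, 4370)], locations)
        W_S = (phi.matrix @ H_L.T) @ rng.random((k, q))
        field = reconstruct(H_L, fit_reprojection(H_L, phi, W_S), rng.random((q, t)))
        assert field.values.shape == (4370, 9600)

    def test_incomplete_sensor_matrix_rejected(self, truth_map, noiseless_sensor):
        import dataclasses

        vals = noiseless_sensor.values.copy()
        vals[0, 0] = np.nan
        broken = dataclasses.replace(noiseless_sensor, values=vals)
        with pytest.raises(ValueError, match="gaps"):
            fuse(truth_map, broken)

    def test_stage_errors_are_labelled(self, segment_map, sensor_matrix, scene):
        with pytest.raises(RuntimeError, match="NMF stage"):
            fuse(segment_map, sensor_matrix, scene.sites, k=10_000, q=4)
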