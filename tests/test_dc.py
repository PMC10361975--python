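import numpy as np
import pytest

from datacollab import dc
from datacollab.dc import (
    Worker,
    anchor_alignment_residual,
    apply_map,
    build_collaborative_dataset,
    compute_collaboration_maps,
    default_intermediate_dim,
    fit_intermediate_map,
    generate_anchor,
)


def oracle_least_squares(M: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Independent normal-equations solve of min ||M G - Z||_F."""
    return np.linalg.solve(M.T @ M, M.T @ Z)


def random_anchor_intermediates(rng, n_workers, r, ls):
    return [rng.normal(size=(r, l)) for l in ls[:n_workers]]


class TestIntermediateMap:
    def test_rank_l_data_reconstructs_losslessly(self):
        rng = np.random.default_rng(0)
        B = rng.normal(size=(3, 6))          # rank-3 configuration in R^6
        X = rng.normal(size=(40, 3)) @ B
        f = fit_intermediate_map(X, "svd", l=3)
        back = apply_map(f, X) @ f.components.T
        assert np.allclose(back, X, atol=1e-8)

    def test_pca_direction_of_points_on_a_line(self):
        t = np.linspace(-2, 3, 25)
        X = np.column_stack([t, 2 * t])      # y = 2x
        f = fit_intermediate_map(X, "pca", l=1)
        expected = np.array([1.0, 2.0]) / np.sqrt(5.0)
        assert np.allclose(f.components[:, 0], expected, atol=1e-10)

    def test_compression_must_reduce_dimension(self):
        X = np.random.default_rng(1).normal(size=(10, 4))
        with pytest.raises(ValueError, match="l < d"):
            fit_intermediate_map(X, "pca", l=4)

    def test_rank_deficiency_rejected(self):
        X = np.ones((10, 4))                 # rank 0 after centering
        with pytest.raises(ValueError, match="rank"):
            fit_intermediate_map(X, "pca", l=2)

    def test_centering_maps_center_to_zero(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 5))
        f = fit_intermediate_map(X, "pca", l=3)
        replicated = np.tile(f.center, (7, 1))
        assert np.allclose(apply_map(f, replicated), 0.0, atol=1e-12)

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 6))
        f = fit_intermediate_map(X, "pca", l=4)
        assert np.allclose(f.components.T @ f.components, np.eye(4), atol=1e-10)

    def test_projection_is_isometric_on_its_span(self):
        rng = np.random.default_rng(4)
        B = np.linalg.qr(rng.normal(size=(5, 4)))[0]  # 4-dim subspace of R^5
        X = rng.normal(size=(25, 4)) @ B.T
        f = fit_intermediate_map(X, "svd", l=4)
        Xt = apply_map(f, X)
        d_orig = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        d_proj = np.linalg.norm(Xt[:, None] - Xt[None, :], axis=2)
        assert np.allclose(d_orig, d_proj, atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        X = np.random.default_rng(5).normal(size=(10, 4))
        f = fit_intermediate_map(X, "pca", l=2)
        with pytest.raises(ValueError, match="columns"):
            apply_map(f, X[:, :3])

    def test_default_dimension(self):
        assert default_intermediate_dim(20) == 15
        assert default_intermediate_dim(4) == 3


class TestAnchor:
    def test_uniform_respects_bounds_and_shape(self):
        a = generate_anchor(3, 50, [(0, 1)] * 3, seed=0)
        assert a.A.shape == (50, 3)
        assert ((a.A >= 0) & (a.A <= 1)).all()

    def test_same_seed_identical(self):
        bounds = [(0, 1), (5, 9)]
        a = generate_anchor(2, 20, bounds, seed=3)
        b = generate_anchor(2, 20, bounds, seed=3)
        assert np.array_equal(a.A, b.A)

    def test_resample_interpolate_stays_on_segment(self):
        ref = np.array([[0.0, 0.0], [1.0, 2.0]])
        a = generate_anchor(2, 100, None, strategy="resample-interpolate",
                            seed=1, reference=ref)
        # every row is a convex combination of the two reference rows
        assert np.allclose(a.A[:, 1], 2 * a.A[:, 0], atol=1e-12)
        assert (a.A[:, 0] >= 0).all() and (a.A[:, 0] <= 1).all()

    def test_missing_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            generate_anchor(3, 10, [(0, 1)] * 2, seed=0)

    def test_anchor_intermediate_shape(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(30, 5))
        f = fit_intermediate_map(X, "pca", l=3)
        a = generate_anchor(5, 17, [(0, 1)] * 5, seed=0)
        assert apply_map(f, a.A).shape == (17, 3)


class TestCollaboration:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            n = int(rng.integers(2, 4))
            r = int(rng.integers(5, 11))
            ls = rng.integers(2, 5, size=n)
            mats = [rng.normal(size=(r, l)) for l in ls]
            k = int(min(ls))
            maps = compute_collaboration_maps(mats, k=k)
            for M, g in zip(mats, maps):
                G_oracle = oracle_least_squares(M, g.Z)
                assert np.linalg.norm(g.G - G_oracle) < 1e-8

    def test_single_invertible_worker_reproduces_target(self):
        rng = np.random.default_rng(11)
        Q = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        maps = compute_collaboration_maps([Q], k=4)
        assert np.allclose(Q @ maps[0].G, maps[0].Z, atol=1e-10)
        assert anchor_alignment_residual(maps, [Q]) == 0.0

    def test_identical_workers_align_exactly(self):
        rng = np.random.default_rng(12)
        M = rng.normal(size=(8, 3))
        maps = compute_collaboration_maps([M, M], k=3)
        assert np.allclose(maps[0].G, maps[1].G)
        assert anchor_alignment_residual(maps, [M, M]) < 1e-10

    def test_target_is_orthonormal(self):
        rng = np.random.default_rng(13)
        mats = random_anchor_intermediates(rng, 3, 9, [3, 4, 2])
        maps = compute_collaboration_maps(mats, k=2)
        Z = maps[0].Z
        assert np.allclose(Z.T @ Z, np.eye(2), atol=1e-10)

    def test_k_above_min_dimension_rejected(self):
        rng = np.random.default_rng(14)
        mats = random_anchor_intermediates(rng, 2, 8, [3, 2])
        with pytest.raises(ValueError, match="k must"):
            compute_collaboration_maps(mats, k=3)

    def test_rank_deficiency_rejected_with_diagnostic(self):
        M = np.zeros((6, 3))
        M[:, 0] = 1.0                       # rank 1
        with pytest.raises(ValueError, match="rank"):
            compute_collaboration_maps([M, np.random.default_rng(0).normal(size=(6, 3))], k=2)

    def test_perturbing_optimal_map_increases_residuals(self):
        rng = np.random.default_rng(15)
        mats = random_anchor_intermediates(rng, 2, 10, [4, 4])
        maps = compute_collaboration_maps(mats, k=3)
        base_fit = np.linalg.norm(mats[0] @ maps[0].G - maps[0].Z)
        base_pair = anchor_alignment_residual(maps, mats)
        G_pert = maps[0].G.copy()
        G_pert[0, 0] += 1.0
        perturbed = [dc.CollaborationMap(G=G_pert, Z=maps[0].Z), maps[1]]
        assert np.linalg.norm(mats[0] @ G_pert - maps[0].Z) > base_fit
        assert anchor_alignment_residual(perturbed, mats) > base_pair

    def test_output_dimension_is_k_for_heterogeneous_workers(self):
        rng = np.random.default_rng(16)
        X1, X2 = rng.normal(size=(12, 6)), rng.normal(size=(15, 6))
        w1 = Worker(X1, np.zeros(12), l=4)
        w2 = Worker(X2, np.zeros(15), l=5)
        anchor = generate_anchor(6, 20, [(-2, 2)] * 6, seed=2)
        maps = compute_collaboration_maps(
            [w1.anchor_intermediate(anchor), w2.anchor_intermediate(anchor)]
        )
        coll = build_collaborative_dataset(
            [w1.intermediate(), w2.intermediate()],
            [w1.y, w2.y], maps,
        )
        assert maps[0].k == 4
        assert coll.X.shape == (27, 4)


class TestStacking:
    def test_shapes_and_provenance(self):
        rng = np.random.default_rng(20)
        mats = [rng.normal(size=(5, 3)), rng.normal(size=(7, 3))]
        anc = random_anchor_intermediates(rng, 2, 9, [3, 3])
        maps = compute_collaboration_maps(anc, k=3)
        coll = build_collaborative_dataset(
            mats, [np.zeros(5), np.ones(7)], maps, ["a", "b"])
        assert coll.X.shape == (12, 3)
        assert (coll.provenance == "a").sum() == 5
        assert (coll.provenance == "b").sum() == 7
        assert coll.y.sum() == 7

    def test_identical_workers_give_identical_blocks(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(10, 5))
        y = (rng.random(10) < 0.4).astype(int)
        w1 = Worker(X, y, l=3)
        w2 = Worker(X, y, l=3)
        anchor = generate_anchor(5, 12, [(-3, 3)] * 5, seed=4)
        anc = [w1.anchor_intermediate(anchor), w2.anchor_intermediate(anchor)]
        maps = compute_collaboration_maps(anc)
        coll = build_collaborative_dataset(
            [w1.intermediate(), w2.intermediate()], [y, y], maps)
        assert np.array_equal(coll.X[:10], coll.X[10:])
        assert anchor_alignment_residual(maps, anc) < 1e-10

    def test_mismatched_k_rejected(self):
        rng = np.random.default_rng(22)
        g1 = dc.CollaborationMap(G=rng.normal(size=(3, 2)),
                                 Z=rng.normal(size=(8, 2)))
        g2 = dc.CollaborationMap(G=rng.normal(size=(3, 3)),
                                 Z=rng.normal(size=(8, 3)))
        with pytest.raises(ValueError, match="mismatched"):
            build_collaborative_dataset(
                [rng.normal(size=(4, 3))] * 2, [np.zeros(4)] * 2, [g1, g2])


class TestSerialisation:
    def test_artifact_roundtrip(self, tmp_path):
        rng = np.random.default_rng(40)
        X = rng.normal(size=(20, 5))
        f = fit_intermediate_map(X, "pca", l=3, fitted_on="w0")
        anchor = generate_anchor(5, 8, [(-1, 1)] * 5, seed=2)
        maps = compute_collaboration_maps([apply_map(f, anchor.A)], k=2)
        for name, obj in (("f.npz", f), ("anc.npz", anchor),
                          ("g.npz", maps[0]),
                          ("xt.npz", apply_map(f, X))):
            path = tmp_path / name
            dc.save_artifact(obj, path)
            back = dc.load_artifact(path)
            if isinstance(obj, np.ndarray):
                assert np.array_equal(back, obj)
            elif hasattr(obj, "components"):
                assert back.method == obj.method
                assert np.array_equal(back.components, obj.components)
                assert np.array_equal(back.center, obj.center)
            elif hasattr(obj, "A"):
                assert np.array_equal(back.A, obj.A)
                assert (back.strategy, back.seed) == (obj.strategy, obj.seed)
            else:
                assert np.array_equal(back.G, obj.G)
                assert np.array_equal(back.Z, obj.Z)

    def test_unknown_object_rejected(self, tmp_path):
        with pytest.raises(TypeError):
            dc.save_artifact({"not": "supported"}, tmp_path / "x.npz")


class TestConfidentialitySurface:
    def test_worker_exposes_no_raw_data(self):
        X = np.random.default_rng(30).normal(size=(10, 4))
        w = Worker(X, np.zeros(10), name="w", l=2)
        public = [a for a in vars(w) if not a.startswith("_")]
        assert set(public) <= {"y", "name"}
        assert not hasattr(w, "X")

    def test_master_side_needs_only_intermediates(self):
        """The full master pipeline runs from shared artefacts alone:
        anchor intermediates, worker intermediates and labels."""
        rng = np.random.default_rng(31)
        workers = [Worker(rng.normal(size=(12, 5)), rng.integers(0, 2, 12), l=3)
                   for _ in range(2)]
        anchor = generate_anchor(5, 10, [(-2, 2)] * 5, seed=9)
        shared = {
            "anchor_intermediates": [w.anchor_intermediate(anchor) for w in workers],
            "intermediates": [w.intermediate() for w in workers],
            "labels": [w.y for w in workers],
        }
        maps = compute_collaboration_maps(shared["anchor_intermediates"])
        coll = build_collaborative_dataset(
            shared["intermediates"], shared["labels"], maps)
        assert coll.X.shape[0] == 24
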