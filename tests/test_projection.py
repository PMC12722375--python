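"""Coordinate regression, tree snapping, KNN selection, projection
determinism, similarity, and transition matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ecgtree.ddrtree import PrincipalTree, minimum_spanning_tree
from ecgtree.projection import (PAPER_2024_XGB, ProjectionModel,
                                build_projection_model, fit_dim_regressors,
                                fit_knn_assigner, nearest_point_similarity,
                                project_external, snap_to_tree,
                                transition_matrices)


def _toy_tree(seed=0, K=12):
    Y = np.random.default_rng(seed).normal(size=(2, K))
    return PrincipalTree(X=np.zeros((2, K)), W=np.eye(2), Z=Y, Y=Y,
                         B=minimum_spanning_tree(Y), R=np.eye(K))


class TestDimRegressors:
    def test_noiseless_linear_target_high_r2(self):
        rng = np.random.default_rng(0)
        lat = rng.normal(size=(600, 10))
        w = rng.normal(size=(10, 2))
        coords = lat @ w
        _, met = fit_dim_regressors(lat, coords, params=PAPER_2024_XGB, seed=0)
        assert min(met["r2"]) >= 0.8

    def test_shuffled_labels_destroy_signal(self):
        rng = np.random.default_rng(1)
        lat = rng.normal(size=(400, 10))
        coords = rng.permutation(lat @ rng.normal(size=(10, 2)))
        _, met = fit_dim_regressors(lat, coords, params=PAPER_2024_XGB, seed=0)
        assert max(met["r2"]) <= 0.1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_dim_regressors(np.zeros((10, 2)), np.zeros((10, 2)), grid={})

    def test_grid_search_contains_tuned_config(self):
        rng = np.random.default_rng(2)
        lat = rng.normal(size=(150, 5))
        coords = lat @ rng.normal(size=(5, 2))
        grid = {"max_depth": [5], "subsample": [0.6], "colsample_bytree": [0.6],
                "learning_rate": [0.1], "n_estimators": [50]}
        _, met = fit_dim_regressors(lat, coords, grid=grid, seed=0, cv_folds=3)
        assert met["best_params"][0]["max_depth"] == 5


class TestSnap:
    def test_point_on_edge_unchanged(self):
        t = _toy_tree()
        e = t.edges()[0]
        mid = 0.5 * (t.Y[:, e[0]] + t.Y[:, e[1]])
        snapped, moved = snap_to_tree(mid[None], t)
        np.testing.assert_allclose(snapped[0], mid, atol=1e-12)
        assert moved[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_over_edges(self):
        t = _toy_tree(seed=3, K=11)       # 10 edges
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(20, 2)) * 2
        snapped, moved = snap_to_tree(pts, t)
        for p, s, m in zip(pts, snapped, moved):
            best = np.inf
            for i, j in t.edges():
                a, b = t.Y[:, i], t.Y[:, j]
                ab = b - a
                tt = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
                best = min(best, np.linalg.norm(p - (a + tt * ab)))
            assert m == pytest.approx(best, abs=1e-12)

    def test_equidistant_tiebreak_smaller_edge(self):
        # symmetric V: edges (0,1) and (0,2); the apex bisector is equidistant
        Y = np.array([[0.0, -1.0, 1.0], [0.0, -1.0, -1.0]])
        B = np.zeros((3, 3))
        B[0, 1] = B[1, 0] = B[0, 2] = B[2, 0] = 1.0
        t = PrincipalTree(X=np.zeros((2, 3)), W=np.eye(2), Z=Y, Y=Y, B=B,
                          R=np.eye(3))
        snapped, _ = snap_to_tree(np.array([[0.0, -1.0]]), t)
        # projects onto edge (0,1), the lexicographically smaller one
        assert snapped[0, 0] <= 0.0


class TestKNN:
    def test_separated_groups_f1_one_at_k1(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (40, 2)), rng.normal(5, 0.1, (40, 2))])
        y = np.array([1] * 40 + [2] * 40)
        clf, k, table = fit_knn_assigner(X, y, k_range=range(1, 20), folds=5)
        assert k == 1
        assert table.iloc[0]["macro_f1"] == 1.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2))
        y = rng.integers(1, 4, 300)
        _, _, table = fit_knn_assigner(X, y, k_range=range(1, 30, 5), folds=5)
        assert table["macro_f1"].max() < 0.55

    def test_macro_f1_matches_hand_computation(self):
        from sklearn.metrics import f1_score
        yt = np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3])
        yp = np.array([1, 1, 2, 1, 2, 2, 1, 2, 3, 3, 3, 1])
        def prf(c):
            tp = np.sum((yp == c) & (yt == c))
            p = tp / np.sum(yp == c)
            r = tp / np.sum(yt == c)
            return 2 * p * r / (p + r)
        assert f1_score(yt, yp, average="macro") == pytest.approx(
            np.mean([prf(c) for c in (1, 2, 3)]))

    def test_k_range_truncated_with_warning(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 2))
        y = np.array([1, 2, 3] * 10)
        with pytest.warns(UserWarning, match="truncated"):
            _, k, _ = fit_knn_assigner(X, y, k_range=range(1, 200), folds=3)
        assert k <= 20


class TestProjectExternal:
    def _model(self):
        rng = np.random.default_rng(0)
        K = 10
        t = _toy_tree(seed=5, K=K)
        lat = rng.normal(size=(300, 6))
        w = rng.normal(size=(6, 2))
        coords = lat @ w * 0.3
        # build a projection model around a synthetic mapping
        t2 = PrincipalTree(X=np.zeros((2, K)), W=np.eye(2), Z=t.Y, Y=t.Y,
                           B=t.B, R=np.eye(K))
        pheno = 1 + (t.Y[0] > 0).astype(int)
        mean, sd, keep = lat.mean(0), lat.std(0), np.ones(6, bool)
        from ecgtree.projection import _make_xgb
        regs = [_make_xgb(PAPER_2024_XGB, 0).fit(lat, coords[:, d])
                for d in range(2)]
        from sklearn.neighbors import KNeighborsClassifier
        knn = KNeighborsClassifier(1).fit(t.Y.T, pheno)
        return ProjectionModel(regs, (mean, sd, keep), t2, knn, 1, True), lat

    def test_batch_vs_stream_bit_equality(self):
        model, lat = self._model()
        batch = project_external(model, lat[:20])
        rows = pd.concat([project_external(model, lat[i:i + 1])
                          for i in range(20)], ignore_index=True)
        pd.testing.assert_frame_equal(batch, rows)

    def test_duplicated_record_identical(self):
        model, lat = self._model()
        out = project_external(model, np.vstack([lat[0], lat[0]]))
        assert out.iloc[0].equals(out.iloc[1])

    def test_dimension_mismatch_rejected(self):
        model, lat = self._model()
        with pytest.raises(ValueError, match="dimension"):
            project_external(model, lat[:, :4])


class TestSimilarity:
    def test_identical_embeddings_rho_one(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(20, 2))
        lat = rng.normal(size=(20, 8))
        rhos = nearest_point_similarity(emb, lat, emb, lat)
        np.testing.assert_allclose(rhos, 1.0)

    def test_five_point_fixture_matches_rank_formula(self):
        emb_a = np.array([[0, 0], [1, 0], [2, 0], [3, 0], [4, 0.0]])
        lat_a = np.array([[1, 2, 3], [3, 1, 2], [2, 3, 1], [1, 3, 2], [2, 1, 3.0]])
        emb_b = emb_a + 0.01
        lat_b = lat_a[::-1]
        from scipy.stats import spearmanr
        rhos = nearest_point_similarity(emb_a, lat_a, emb_b, lat_b)
        for i in range(5):
            assert rhos[i] == pytest.approx(
                spearmanr(lat_a[i], lat_b[i]).statistic)


class TestTransitions:
    def test_no_reassignment_identity(self):
        pairs = pd.DataFrame({"record_id_from": ["a", "b"],
                              "record_id_to": ["a2", "b2"]})
        assign = {"a": 1, "a2": 1, "b": 2, "b2": 2}
        mat, n = transition_matrices(pairs, assign, groups=[1, 2])
        np.testing.assert_allclose(mat.to_numpy(), np.eye(2))

    def test_counting_proportions(self):
        pairs = pd.DataFrame({"record_id_from": [f"a{i}" for i in range(10)],
                              "record_id_to": [f"b{i}" for i in range(10)]})
        assign = {f"a{i}": 1 for i in range(10)}
        assign.update({f"b{i}": (1 if i < 7 else 3) for i in range(10)})
        mat, n = transition_matrices(pairs, assign, groups=[1, 2, 3, 4, 5])
        np.testing.assert_allclose(mat.loc[1].to_numpy(),
                                   [0.7, 0, 0.3, 0, 0])
        assert n[0] == 10

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_rows_stochastic(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        pairs = pd.DataFrame({"record_id_from": [f"x{i}" for i in range(n)],
                              "record_id_to": [f"y{i}" for i in range(n)]})
        assign = {f"x{i}": int(rng.integers(1, 4)) for i in range(n)}
        assign.update({f"y{i}": int(rng.integers(1, 4)) for i in range(n)})
        mat, npairs = transition_matrices(pairs, assign, groups=[1, 2, 3])
        for g in range(3):
            if npairs[g] > 0:
                assert mat.iloc[g].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_direction_warns(self):
        with pytest.warns(UserWarning):
            mat, n = transition_matrices(
                pd.DataFrame(columns=["record_id_from", "record_id_to"]),
                {"a": 1}, groups=[1])
        assert (n == 0).all()


class TestModelPersistence:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        t = _toy_tree(seed=5, K=10)
        lat = rng.normal(size=(200, 6))
        coords = lat @ rng.normal(size=(6, 2)) * 0.3
        t2 = PrincipalTree(X=np.zeros((2, 10)), W=np.eye(2), Z=t.Y, Y=t.Y,
                           B=t.B, R=np.eye(10))
        from ecgtree.projection import _make_xgb
        from sklearn.neighbors import KNeighborsClassifier
        regs = [_make_xgb(PAPER_2024_XGB, 0).fit(lat, coords[:, d])
                for d in range(2)]
        knn = KNeighborsClassifier(1).fit(t.Y.T, 1 + (t.Y[0] > 0).astype(int))
        pm = ProjectionModel(regs, (lat.mean(0), lat.std(0), np.ones(6, bool)),
                             t2, knn, 1, True)
        path = tmp_path / "pm.pkl"
        pm.save(path)
        back = ProjectionModel.load(path)
        a = project_external(pm, lat[:10])
        b = project_external(back, lat[:10])
        pd.testing.assert_frame_equal(a, b)
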