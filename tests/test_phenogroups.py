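"""Sub-branch decomposition, silhouette/ARI oracles, pseudotime, stability."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from ecgtree.ddrtree import (DDRTreeParams, PrincipalTree, fit_ddrtree,
                             minimum_spanning_tree, normalize_features)
from ecgtree.phenogroups import (compute_pseudotime, consolidate_branches,
                                 extract_subbranches, phenogroup_mean_beat,
                                 silhouette_mean, tree_stability)


def _tree_from_Y(Y, B=None):
    K = Y.shape[1]
    B = minimum_spanning_tree(Y) if B is None else B
    return PrincipalTree(X=np.zeros((3, K)), W=np.zeros((3, 2)),
                         Z=Y + 1e-3, Y=Y, B=B, R=np.eye(K))


class TestSubbranches:
    def test_path_graph_single_subbranch(self):
        Y = np.stack([np.arange(10.0), np.zeros(10)])
        sc, ss = extract_subbranches(_tree_from_Y(Y))
        assert len(np.unique(sc)) == 1

    def test_y_topology_three_subbranches(self):
        Y = np.array([[0, 0], [1, 0], [2, 0], [-0.5, 0.9], [-1, 1.8],
                      [-0.5, -0.9], [-1, -1.8]]).T
        sc, _ = extract_subbranches(_tree_from_Y(Y))
        assert len(np.unique(sc)) == 3

    def test_star_five_leaves_five_subbranches(self):
        # explicit star adjacency: node 0 centre, 5 leaves
        Y = np.array([[0, 0], [1, 0], [0, 1], [-1, 0], [0, -1], [1, 1.0]]).T
        B = np.zeros((6, 6))
        for leaf in range(1, 6):
            B[0, leaf] = B[leaf, 0] = 1.0
        sc, _ = extract_subbranches(_tree_from_Y(Y, B))
        assert len(np.unique(sc)) == 5

    def test_two_centroid_tree_degenerate(self):
        Y = np.array([[0.0, 1.0], [0.0, 0.0]])
        sc, ss = extract_subbranches(_tree_from_Y(Y))
        assert (sc == 0).all()

    def test_samples_inherit_nearest_centroid_subbranch(self):
        Y = np.array([[0, 0], [1, 0], [2, 0], [-0.5, 0.9], [-1, 1.8],
                      [-0.5, -0.9], [-1, -1.8]]).T
        t = _tree_from_Y(Y)
        sc, ss = extract_subbranches(t)
        np.testing.assert_array_equal(ss, sc[t.R.argmax(axis=1)])


class TestSilhouette:
    def test_coincident_far_clusters_score_one(self):
        coords = np.array([[0, 0], [0, 0], [10, 10], [10, 10.0]])
        assert silhouette_mean(coords, [0, 0, 1, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_random_labels_on_one_blob_near_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(500, 2))
        labels = rng.integers(0, 2, 500)
        assert abs(silhouette_mean(coords, labels)) < 0.1

    def test_matches_brute_force_formula_on_fixture(self):
        coords = np.array([[0, 0], [0, 1], [1, 0], [5, 5], [5, 6], [6, 5.0]])
        labels = np.array([0, 0, 0, 1, 1, 1])
        d = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
        svals = []
        for i in range(6):
            same = (labels == labels[i])
            a = d[i, same & (np.arange(6) != i)].mean()
            b = min(d[i, labels == l].mean()
                    for l in np.unique(labels) if l != labels[i])
            svals.append((b - a) / max(a, b))
        assert silhouette_mean(coords, labels) == pytest.approx(np.mean(svals))

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_mean(np.zeros((4, 2)), [1, 1, 1, 1])


class TestConsolidate:
    def _two_cloud_tree(self):
        # two distant star-shaped clouds joined by a junction-to-junction
        # bridge edge: several sub-branches per cloud, none spanning the gap
        rng = np.random.default_rng(0)
        arms = []
        for cx in (0.0, 6.0):
            arms += [[cx, 0], [cx - 0.5, 0.1], [cx + 0.5, 0.1], [cx, 0.5]]
        Y = np.array(arms).T
        K = Y.shape[1]
        B = np.zeros((K, K))
        for base in (0, 4):                      # stars at nodes 0 and 4
            for leaf in (1, 2, 3):
                B[base, base + leaf] = B[base + leaf, base] = 1.0
        B[0, 4] = B[4, 0] = 1.0                  # the bridge
        n = 150
        c1 = rng.normal([0, 0.2], 0.3, (n, 2))
        c2 = rng.normal([6, 0.2], 0.3, (n, 2))
        Z = np.vstack([c1, c2]).T
        d2 = ((Z.T[:, None] - Y.T[None]) ** 2).sum(-1)
        R = np.exp(-(d2 - d2.min(1, keepdims=True)) / 0.1)
        R /= R.sum(1, keepdims=True)
        return PrincipalTree(X=np.vstack([Z, np.zeros((1, 2 * n))]),
                             W=np.zeros((3, 2)), Z=Z, Y=Y, B=B, R=R)

    def test_two_separated_clouds_choose_k2(self):
        sol = consolidate_branches(self._two_cloud_tree())
        assert sol.chosen_k == 2
        assert sol.silhouette_by_k[2] > 0.9

    def test_partition_refines_subbranches(self):
        tree = self._two_cloud_tree()
        sol = consolidate_branches(tree)
        for s in np.unique(sol.sub_branch_of_sample):
            groups = np.unique(sol.phenogroup_of_sample[sol.sub_branch_of_sample == s])
            assert len(groups) == 1

    def test_chosen_k_is_silhouette_argmax(self):
        sol = consolidate_branches(self._two_cloud_tree())
        if sol.silhouette_by_k:
            best = max(sol.silhouette_by_k.items(),
                       key=lambda kv: (kv[1], -kv[0]))[0]
            assert sol.chosen_k == best


class TestPseudotime:
    def test_path_root_is_centre_and_monotone(self):
        Y = np.stack([np.arange(10.0), np.zeros(10)])
        t = _tree_from_Y(Y)
        pt = compute_pseudotime(t)
        assert pt.root_centroid == 4
        left = pt.centroid_geodesic[:5]
        right = pt.centroid_geodesic[4:]
        assert np.all(np.diff(left) < 0) and np.all(np.diff(right) > 0)

    def test_geodesic_oracle(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(2, 12))
        t = _tree_from_Y(Y)
        pt = compute_pseudotime(t, root=0)
        from scipy.sparse.csgraph import dijkstra
        d2 = ((Y.T[:, None] - Y.T[None]) ** 2).sum(-1)
        W = t.B * np.sqrt(d2)
        ref = dijkstra(W, directed=False, indices=0)
        np.testing.assert_allclose(pt.centroid_geodesic, ref, atol=1e-12)

    def test_root_samples_pseudotime_is_offset_only(self):
        Y = np.stack([np.arange(5.0), np.zeros(5)])
        t = _tree_from_Y(Y)
        pt = compute_pseudotime(t, root=2)
        offset = np.linalg.norm(t.Z[:, 2] - Y[:, 2])
        assert pt.pseudotime_of_sample[2] == pytest.approx(offset)

    def test_triangle_inequality_on_centroids(self):
        rng = np.random.default_rng(9)
        Y = rng.normal(size=(2, 10))
        t = _tree_from_Y(Y)
        from scipy.sparse.csgraph import shortest_path
        d2 = ((Y.T[:, None] - Y.T[None]) ** 2).sum(-1)
        geo = shortest_path(t.B * np.sqrt(d2), directed=False)
        for a in range(10):
            for b in range(10):
                for c in range(10):
                    assert geo[a, c] <= geo[a, b] + geo[b, c] + 1e-9


class TestStabilityAndARI:
    def test_identical_refit_gives_ari_one(self):
        a = np.array([1, 1, 2, 2, 3, 3])
        assert adjusted_rand_score(a, a) == 1.0

    def test_random_labels_ari_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 500)
        b = rng.permutation(a)
        assert abs(adjusted_rand_score(a, b)) < 0.05

    def test_ari_matches_contingency_closed_form(self):
        a = np.array([0, 0, 1, 1, 1, 2])
        b = np.array([0, 0, 0, 1, 1, 1])
        from scipy.special import comb
        ct = np.zeros((3, 2))
        for x, y in zip(a, b):
            ct[x, y] += 1
        sum_comb = comb(ct, 2).sum()
        sum_a = comb(ct.sum(1), 2).sum()
        sum_b = comb(ct.sum(0), 2).sum()
        n = comb(6, 2)
        expected = (sum_comb - sum_a * sum_b / n) / \
                   (0.5 * (sum_a + sum_b) - sum_a * sum_b / n)
        assert adjusted_rand_score(a, b) == pytest.approx(expected)

    def test_bootstrap_stability_runs_and_reports(self):
        rng = np.random.default_rng(1)
        n = 120
        X = np.hstack([rng.normal(0, 0.3, (3, n)), rng.normal(3, 0.3, (3, n))])
        res = tree_stability(X, DDRTreeParams(n_centroids=20, seed=0),
                             n_resamples=3, seed=5, k_range=range(2, 5))
        assert len(res["aris"]) == 3
        assert -1 <= res["median"] <= 1


class TestMeanBeat:
    def test_identical_beats_zero_sd_and_lead_algebra(self):
        beat = np.random.default_rng(0).normal(size=(8, 320))
        beats = np.stack([beat] * 5)
        out = phenogroup_mean_beat(beats, np.ones(5))
        g = out[1]
        assert g["n"] == 5
        np.testing.assert_allclose(g["sd"], 0.0, atol=1e-12)
        np.testing.assert_allclose(g["median"][2], g["median"][1] - g["median"][0],
                                   atol=1e-12)

    def test_sd_band_grows_with_noise(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(8, 320))
        widths = []
        for sd in (0.01, 0.05, 0.2):
            beats = base[None] + rng.normal(0, sd, size=(20, 8, 320))
            out = phenogroup_mean_beat(beats, np.ones(20))
            widths.append(out[1]["sd"].mean())
        assert widths[0] < widths[1] < widths[2]


class TestNewick:
    def test_linkage_renders_valid_newick(self):
        from scipy.cluster.hierarchy import linkage
        from ecgtree.phenogroups import linkage_to_newick
        rng = np.random.default_rng(0)
        Z = linkage(rng.normal(size=(6, 2)), method="average")
        nwk = linkage_to_newick(Z)
        assert nwk.endswith(";")
        assert nwk.count("(") == 5           # n-1 internal nodes
        for i in range(6):
            assert f"sb{i}" in nwk
        # parseable by a standard phylogenetics reader
        import io as _io
        from Bio import Phylo
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        assert tree.count_terminals() == 6
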