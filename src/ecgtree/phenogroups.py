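"""Phenogroup consolidation over the principal tree.

Decomposes the centroid spanning tree into sub-branches (maximal paths
between nodes of degree != 2), consolidates them into phenogroups by
agglomerative clustering (Euclidean, average linkage) of sub-branch
coordinate summaries with silhouette-based selection of the cluster count,
computes pseudotime (geodesic distance from the tree centre), and assesses
internal stability by bootstrap refits compared through the adjusted Rand
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.sparse.csgraph import shortest_path
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .ddrtree import DDRTreeParams, PrincipalTree, fit_ddrtree
from .synthetic import derive_limb_leads


# --------------------------------------------------------------------------
# sub-branch decomposition


def extract_subbranches(tree: PrincipalTree) -> tuple[np.ndarray, np.ndarray]:
    """Label centroids and samples with sub-branch ids.

    Branch nodes are centroids of MST degree != 2; a sub-branch is a maximal
    path between consecutive branch nodes/leaves.  Interior (degree-2) nodes
    belong to their chain; branch nodes are assigned to the incident
    sub-branch of smallest id.  Samples inherit the sub-branch of their
    nearest centroid.  Returns (subbranch_of_centroid, subbranch_of_sample).
    """
    B = tree.B
    K = B.shape[0]
    deg = B.sum(axis=1).astype(int)
    adj = [np.where(B[i] > 0)[0].tolist() for i in range(K)]

    if K <= 2:
        sub_c = np.zeros(K, dtype=int)
    else:
        branch_nodes = set(np.where(deg != 2)[0].tolist())
        if not branch_nodes:       # cannot happen for a tree, but be safe
            branch_nodes = {0}
        # walk each chain leaving a branch node; each chain = one sub-branch
        paths = []
        visited_edges = set()
        for b in sorted(branch_nodes):
            for nb in adj[b]:
                if (b, nb) in visited_edges:
                    continue
                path = [b]
                prev, cur = b, nb
                visited_edges.add((b, nb))
                visited_edges.add((nb, b))
                while True:
                    path.append(cur)
                    if cur in branch_nodes:
                        break
                    nxt = [x for x in adj[cur] if x != prev][0]
                    visited_edges.add((cur, nxt))
                    visited_edges.add((nxt, cur))
                    prev, cur = cur, nxt
                paths.append(path)
        # deterministic sub-branch ids: order chains by smallest interior
        # centroid (fall back to path ends), then lexicographically
        paths.sort(key=lambda p: (min(p), p[0], p[-1]))
        sub_c = np.full(K, -1, dtype=int)
        for sid, path in enumerate(paths):
            for node in path:
                if node in branch_nodes:
                    if sub_c[node] < 0:      # smallest incident sub-branch id
                        sub_c[node] = sid
                else:
                    sub_c[node] = sid
        # isolated-from-chains safety (single-node tree components)
        sub_c[sub_c < 0] = 0
        # short chains whose endpoints were claimed by smaller ids can end
        # up owning no centroid; densify ids over the non-empty sub-branches
        _, sub_c = np.unique(sub_c, return_inverse=True)

    nearest = tree.R.argmax(axis=1)
    return sub_c, sub_c[nearest]


# --------------------------------------------------------------------------
# silhouette


def silhouette_mean(coords: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette (b - a)/max(a, b) over points; singletons score 0."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette needs >= 2 clusters")
    return float(silhouette_score(np.asarray(coords, dtype=float), labels))


# --------------------------------------------------------------------------
# consolidation


@dataclass
class PhenogroupSolution:
    sub_branch_of_centroid: np.ndarray
    sub_branch_of_sample: np.ndarray
    phenogroup_of_subbranch: np.ndarray     # sub-branch id -> phenogroup 1..G
    phenogroup_of_sample: np.ndarray        # 1..G
    silhouette_by_k: dict[int, float] = field(default_factory=dict)
    chosen_k: int = 0
    linkage_record: np.ndarray | None = None


def consolidate_branches(tree: PrincipalTree,
                         k_range: range | tuple = range(2, 11)
                         ) -> PhenogroupSolution:
    """Consolidate sub-branches into phenogroups with silhouette selection.

    Sub-branch summaries are the min-max-normalised mean coordinates of each
    sub-branch's centroids; these are clustered agglomeratively (Euclidean,
    average linkage).  For each candidate k the dendrogram is cut, sample
    labels are induced through their sub-branch, and the mean silhouette over
    sample coordinates is computed; the k with the highest silhouette wins
    (ties toward smaller k).  Phenogroups are labelled 1..G ordered by their
    mean (dim1, dim2) position for determinism.
    """
    sub_c, sub_s = extract_subbranches(tree)
    n_sub = int(sub_c.max()) + 1
    coords_s = tree.Z.T                                   # samples x dim

    if n_sub < 2:
        warnings.warn("single sub-branch: one phenogroup")
        return PhenogroupSolution(sub_c, sub_s, np.ones(n_sub, dtype=int),
                                  np.ones(len(sub_s), dtype=int), {}, 1, None)

    summaries = np.stack([tree.Y[:, sub_c == s].mean(axis=1)
                          for s in range(n_sub)])
    rng_span = summaries.max(axis=0) - summaries.min(axis=0)
    rng_span[rng_span == 0] = 1.0
    summaries_mm = (summaries - summaries.min(axis=0)) / rng_span

    ks = [k for k in k_range]
    if max(ks) > n_sub:
        warnings.warn(f"k_range truncated to the {n_sub} sub-branches")
        ks = [k for k in ks if k <= n_sub]

    Zlink = linkage(summaries_mm, method="average", metric="euclidean")
    sil_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        lab_sub = cut_tree(Zlink, n_clusters=k).ravel()
        lab_samples = lab_sub[sub_s]
        if len(np.unique(lab_samples)) < 2:
            continue
        sil_by_k[k] = silhouette_mean(coords_s, lab_samples)
        labels_by_k[k] = lab_sub
    if not sil_by_k:
        raise RuntimeError("no valid clustering in k_range")
    chosen_k = min((k for k in sil_by_k),
                   key=lambda k: (-sil_by_k[k], k))
    lab_sub = labels_by_k[chosen_k]

    # deterministic 1..G labels ordered by phenogroup mean position
    order_key = []
    for g in range(chosen_k):
        members = np.where(lab_sub == g)[0]
        pos = summaries[members].mean(axis=0)
        order_key.append((pos[0], pos[1] if pos.size > 1 else 0.0, g))
    relabel = {old: new + 1 for new, (_, _, old)
               in enumerate(sorted(order_key))}
    pheno_sub = np.array([relabel[g] for g in lab_sub])
    return PhenogroupSolution(sub_c, sub_s, pheno_sub, pheno_sub[sub_s],
                              sil_by_k, chosen_k, Zlink)


def linkage_to_newick(Z: np.ndarray, labels: list[str] | None = None) -> str:
    """Render a scipy linkage matrix as a Newick string (for inspection)."""
    n = Z.shape[0] + 1
    if labels is None:
        labels = [f"sb{i}" for i in range(n)]
    nodes: dict[int, tuple[str, float]] = {i: (labels[i], 0.0) for i in range(n)}
    for i, (a, b, height, _) in enumerate(Z):
        (sa, ha), (sb, hb) = nodes[int(a)], nodes[int(b)]
        s = f"({sa}:{height - ha:.6g},{sb}:{height - hb:.6g})"
        nodes[n + i] = (s, float(height))
    return nodes[n + Z.shape[0] - 1][0] + ";"


# --------------------------------------------------------------------------
# pseudotime


@dataclass
class PseudotimeField:
    root_centroid: int
    pseudotime_of_sample: np.ndarray
    centroid_geodesic: np.ndarray          # geodesic distance root -> centroid


def compute_pseudotime(tree: PrincipalTree, root: int | None = None
                       ) -> PseudotimeField:
    """Geodesic distance from the tree centre along the centroid MST.

    The default root is the tree centre: the centroid minimising the maximum
    geodesic distance to any other centroid (graph 1-centre, smallest index
    on ties).  A sample's pseudotime is the geodesic to its nearest centroid
    plus its Euclidean offset from that centroid.
    """
    Y = tree.Y
    K = Y.shape[1]
    d2 = ((Y.T[:, None, :] - Y.T[None, :, :]) ** 2).sum(-1)
    wadj = tree.B * np.sqrt(np.maximum(d2, 0.0))
    geo = shortest_path(wadj, method="D", directed=False)
    if root is None:
        root = int(np.argmin(geo.max(axis=1)))
    dist_from_root = geo[root]
    nearest = tree.R.argmax(axis=1)
    offset = np.linalg.norm(tree.Z - Y[:, nearest], axis=0)
    return PseudotimeField(root, dist_from_root[nearest] + offset,
                           dist_from_root)


# --------------------------------------------------------------------------
# stability


def tree_stability(X: np.ndarray, params: DDRTreeParams, n_resamples: int = 20,
                   seed: int = 0, k_range=range(2, 11)) -> dict:
    """Bootstrap stability of the phenogroup partition, summarised by ARI.

    Fits a reference tree+phenogroups on X (features x samples), then
    ``n_resamples`` times resamples the samples with replacement, refits, and
    compares phenogroup labels of the records present in both partitions
    (each resampled record counted once).  Returns median and IQR of the ARI
    distribution.
    """
    if n_resamples < 2:
        raise ValueError("need >= 2 resamples")
    ref_tree = fit_ddrtree(X, params)
    ref_labels = consolidate_branches(ref_tree, k_range).phenogroup_of_sample
    rng = np.random.default_rng(seed)
    n = X.shape[1]
    aris = []
    for b in range(n_resamples):
        idx = np.unique(rng.integers(0, n, size=n))
        bp = DDRTreeParams(**{**params.__dict__,
                              "n_centroids": min(params.n_centroids, len(idx)),
                              "seed": params.seed + b + 1})
        t = fit_ddrtree(X[:, idx], bp)
        lab = consolidate_branches(t, k_range).phenogroup_of_sample
        aris.append(adjusted_rand_score(ref_labels[idx], lab))
    aris = np.asarray(aris)
    return {"median": float(np.median(aris)),
            "iqr": (float(np.percentile(aris, 25)),
                    float(np.percentile(aris, 75))),
            "aris": aris}


# --------------------------------------------------------------------------
# representative beats


def phenogroup_mean_beat(beats: np.ndarray, phenogroups: np.ndarray
                         ) -> dict[int, dict[str, np.ndarray]]:
    """Per-group pointwise-median 12-lead display beat with an sd band.

    ``beats``: (n_records, 8, L) median beats (leads I, II, V1-V6); the
    derived limb leads are reconstructed from I and II for display.  Returns
    {group: {"median": (12, L), "sd": (12, L), "n": count}}.
    """
    beats = np.asarray(beats)
    phenogroups = np.asarray(phenogroups)
    out = {}
    for g in np.unique(phenogroups):
        members = beats[phenogroups == g]
        if len(members) == 0:
            warnings.warn(f"phenogroup {g} empty; excluded")
            continue
        med8 = np.median(members, axis=0)
        sd8 = members.std(axis=0)
        twelve = np.stack([derive_limb_leads(m) for m in members])
        out[int(g)] = {"median": derive_limb_leads(med8),
                       "sd": twelve.std(axis=0),
                       "n": len(members)}
    return out
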