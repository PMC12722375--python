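"""Reversed graph embedding principal tree (DDRTree).

Learns, by alternating minimisation, a linear projection W, low-dimensional
sample coordinates Z, centroids Y carrying a spanning tree B, and soft sample
-> centroid assignments R, minimising

    ||X - W Z||^2  +  lambda * sum_{(k,k') in B} ||y_k - y_k'||^2
                   +  gamma * sum_i [ sum_k r_ik ||z_i - y_k||^2
                                      + sigma * r_ik log r_ik ]

Per iteration: (i) B <- Euclidean MST over Y; (ii) R <- row-softmax of
-||z - y||^2 / sigma; (iii) closed-form solves for Y and for (W, Z) via the
top-``dim`` eigenvectors of a projected covariance.  Default regularisers
follow the reference implementation (lambda = 5 * n_samples, sigma = 1e-3,
gamma = 10) with the centroid count as the only routinely changed knob.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh, solve
from sklearn.cluster import KMeans


@dataclass
class DDRTreeParams:
    dim: int = 2
    n_centroids: int = 100
    max_iter: int = 20
    tol: float = 1e-3
    lambda_reg: float | None = None    # default 5 * n_samples
    sigma_soft: float = 1e-3
    gamma_fit: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_soft <= 0 or self.gamma_fit <= 0:
            raise ValueError("regularisers must be positive")
        if self.lambda_reg is not None and self.lambda_reg < 0:
            raise ValueError("lambda_reg must be >= 0")


@dataclass
class PrincipalTree:
    X: np.ndarray                  # features x samples (z-scored input)
    W: np.ndarray                  # features x dim, orthonormal
    Z: np.ndarray                  # dim x samples
    Y: np.ndarray                  # dim x centroids
    B: np.ndarray                  # centroid adjacency (symmetric binary)
    R: np.ndarray                  # samples x centroids, rows sum to 1
    objective_trace: list = field(default_factory=list)
    converged: bool = True
    params: DDRTreeParams | None = None

    @property
    def n_centroids(self) -> int:
        return self.Y.shape[1]

    def edges(self) -> np.ndarray:
        """Sorted (i, j) edge list of the centroid spanning tree."""
        iu, ju = np.where(np.triu(self.B) > 0)
        return np.column_stack([iu, ju])


def normalize_features(latents: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Z-score columns (features) of an (n_samples, n_features) matrix.

    Returns (normalised samples x kept-features, mean, sd, kept_mask); the
    mean/sd are stored for reuse on external cohorts.  Zero-variance features
    are dropped with a warning.
    """
    latents = np.asarray(latents, dtype=float)
    if latents.ndim != 2 or latents.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    if np.isnan(latents).any():
        raise ValueError("missing values not allowed")
    mean = latents.mean(axis=0)
    sd = latents.std(axis=0)       # population sd
    keep = sd > 0
    if not keep.any():
        raise ValueError("all features have zero variance")
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} zero-variance features")
    return (latents[:, keep] - mean[keep]) / sd[keep], mean, sd, keep


def apply_normalization(latents: np.ndarray, mean, sd, keep) -> np.ndarray:
    """Apply stored z-scoring to an external cohort (never refit)."""
    latents = np.asarray(latents, dtype=float)
    return (latents[:, keep] - np.asarray(mean)[keep]) / np.asarray(sd)[keep]


def minimum_spanning_tree(points: np.ndarray) -> np.ndarray:
    """Euclidean MST over columns of a (dim, K) matrix.

    Kruskal with edges sorted by (weight, i, j): deterministic lexicographic
    tie-break.  Duplicate points are allowed (zero-weight edges).
    Returns a symmetric binary (K, K) adjacency.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("need at least 2 points (dim x K)")
    if not np.isfinite(pts).all():
        raise ValueError("points must be finite")
    K = pts.shape[1]
    d2 = _sqdist(pts.T, pts.T)
    iu, ju = np.triu_indices(K, k=1)
    w = d2[iu, ju]
    order = np.lexsort((ju, iu, w))
    parent = np.arange(K)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    B = np.zeros((K, K), dtype=float)
    n_edges = 0
    for e in order:
        a, b = find(iu[e]), find(ju[e])
        if a != b:
            parent[a] = b
            B[iu[e], ju[e]] = B[ju[e], iu[e]] = 1.0
            n_edges += 1
            if n_edges == K - 1:
                break
    return B


def _sqdist(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances between rows of a and rows of b (>= 0)."""
    d = (a * a).sum(1)[:, None] + (b * b).sum(1)[None, :] - 2.0 * a @ b.T
    return np.maximum(d, 0.0)


def _soft_assign(Z: np.ndarray, Y: np.ndarray, sigma: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Row-softmax of -||z - y||^2 / sigma with max-subtraction for stability."""
    d2 = _sqdist(Z.T, Y.T)
    shifted = d2 - d2.min(axis=1, keepdims=True)
    R = np.exp(-shifted / sigma)
    R /= R.sum(axis=1, keepdims=True)
    return R, d2


def ddrtree_objective(tree: PrincipalTree, params: DDRTreeParams | None = None,
                      return_terms: bool = False):
    """Evaluate the reversed-graph-embedding objective for a tree state.

    Terms: reconstruction ||X - WZ||^2, lambda * tree smoothness, gamma *
    soft-assignment distance, gamma*sigma * assignment entropy (sum r log r).
    """
    p = params or tree.params
    lam = p.lambda_reg if p.lambda_reg is not None else 5.0 * tree.X.shape[1]
    recon = float(np.sum((tree.X - tree.W @ tree.Z) ** 2))
    L = np.diag(tree.B.sum(axis=1)) - tree.B
    smooth = float(np.trace(tree.Y @ L @ tree.Y.T))
    d2 = _sqdist(tree.Z.T, tree.Y.T)
    R = np.clip(tree.R, 1e-300, None)
    assign = float(np.sum(tree.R * d2))
    entropy = float(np.sum(tree.R * np.log(R)))
    total = recon + lam * smooth + p.gamma_fit * (assign + p.sigma_soft * entropy)
    if return_terms:
        return total, {"recon": recon, "smooth": smooth, "assign": assign,
                       "entropy": entropy, "lambda": lam}
    return total


def fit_ddrtree(X: np.ndarray, params: DDRTreeParams | None = None
                ) -> PrincipalTree:
    """Fit the principal tree to a normalised (features x samples) matrix.

    Initialisation: Z from the top-``dim`` principal components of X; Y from
    seeded k-means++ on Z (Y = Z when n_centroids == n_samples).  Terminates
    when the relative objective change drops below ``tol``.
    """
    if params is None:
        params = DDRTreeParams()
    X = np.asarray(X, dtype=float)
    D, N = X.shape
    K = params.n_centroids
    if not (2 <= K <= N):
        raise ValueError(f"need 2 <= n_centroids ({K}) <= n_samples ({N})")
    lam = params.lambda_reg if params.lambda_reg is not None else 5.0 * N
    gamma, sigma = params.gamma_fit, params.sigma_soft
    d = params.dim

    # ---- initialisation: PCA scores, then k-means++ centroids
    Xc = X - X.mean(axis=1, keepdims=True)
    cov = Xc @ Xc.T
    vals, vecs = eigh(cov)
    W = vecs[:, ::-1][:, :d]
    # deterministic sign convention: largest-|.| entry of each axis positive
    for j in range(d):
        i = np.argmax(np.abs(W[:, j]))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    Z = W.T @ X
    if K == N:
        Y = Z.copy()
    else:
        km = KMeans(n_clusters=K, init="k-means++", n_init=1,
                    random_state=params.seed).fit(Z.T)
        Y = km.cluster_centers_.T

    trace: list[float] = []
    B = minimum_spanning_tree(Y)
    converged = False
    for it in range(params.max_iter):
        B = minimum_spanning_tree(Y)
        L = np.diag(B.sum(axis=1)) - B
        R, d2 = _soft_assign(Z, Y, sigma)
        Gamma = R.sum(axis=0)                     # diag of Gamma

        # ---- closed-form updates (Y given Z; then W, Z)
        M = (lam / gamma) * L + np.diag(Gamma)    # K x K, SPD
        A = ((gamma + 1.0) / gamma) * M - R.T @ R
        tmp = solve(A, R.T, assume_a="pos").T     # N x K
        # C = X Q with Q = (I + tmp R^T) / (gamma + 1), never forming Q
        C = (X + (X @ tmp) @ R.T) / (gamma + 1.0)
        S = C @ X.T
        vals, vecs = eigh((S + S.T) / 2.0)
        W = vecs[:, ::-1][:, :d]
        for j in range(d):
            i = np.argmax(np.abs(W[:, j]))
            if W[i, j] < 0:
                W[:, j] = -W[:, j]
        Z = W.T @ C
        Y = solve(M, (Z @ R).T, assume_a="pos").T

        if not (np.isfinite(Z).all() and np.isfinite(Y).all()):
            raise FloatingPointError("NaN/inf in DDRTree updates")

        B = minimum_spanning_tree(Y)
        R, _ = _soft_assign(Z, Y, sigma)
        state = PrincipalTree(X=X, W=W, Z=Z, Y=Y, B=B, R=R, params=params)
        obj = ddrtree_objective(state, params)
        trace.append(obj)
        if it > 0 and abs(trace[-2] - obj) < params.tol * abs(trace[-2]):
            converged = True
            break
    if not converged:
        warnings.warn("DDRTree did not converge within max_iter")
    tree = PrincipalTree(X=X, W=W, Z=Z, Y=Y, B=B, R=R,
                         objective_trace=trace, converged=converged,
                         params=params)
    return tree


def embed_samples(tree: PrincipalTree) -> np.ndarray:
    """(n_samples, dim + 1): tree coordinates plus nearest-centroid index.

    Nearest centroid = argmax of the soft-assignment row; ties break toward
    the smaller centroid index (np.argmax convention).
    """
    nearest = tree.R.argmax(axis=1)
    return np.column_stack([tree.Z.T, nearest])
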