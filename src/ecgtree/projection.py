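"""External-cohort projection onto a fitted principal tree.

Coordinates are predicted by per-dimension gradient-boosted regressors
(XGBoost) trained on the derivation cohort's latent features, optionally
snapped to the nearest point of the embedded centroid tree, and phenogroups
are assigned by a supervised KNN classifier whose K is chosen by
cross-validated macro-F1.  Transition matrices quantify phenogroup
reassignment across within-patient rhythm-change ECG pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import f1_score, mean_absolute_error, r2_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from xgboost import XGBRegressor

#: the tuned boosted-regressor hyperparameters shipped as a named config
PAPER_2024_XGB = dict(max_depth=5, subsample=0.6, colsample_bytree=0.6,
                      learning_rate=0.1, n_estimators=200)

#: small default search grid containing the tuned configuration
DEFAULT_GRID = {
    "max_depth": [3, 5],
    "subsample": [0.6, 1.0],
    "colsample_bytree": [0.6, 1.0],
    "learning_rate": [0.1],
    "n_estimators": [200],
}


def _make_xgb(params: dict, seed: int) -> XGBRegressor:
    return XGBRegressor(random_state=seed, n_jobs=1, tree_method="hist",
                        verbosity=0, **params)


@dataclass
class ProjectionModel:
    regressors: list                        # one per tree dimension
    norm: tuple                             # (mean, sd, keep) from derivation
    tree: object                            # fitted PrincipalTree
    knn: KNeighborsClassifier | None = None
    knn_k: int = 1
    snap: bool = True
    cv_metrics: dict = field(default_factory=dict)

    def save(self, path) -> None:
        """Serialise with the embedded normalisation parameters."""
        import pickle

        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "ProjectionModel":
        import pickle

        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError(f"{path} does not hold a ProjectionModel")
        return model


def fit_dim_regressors(latents: np.ndarray, coords: np.ndarray,
                       grid: dict | None = None,
                       params: dict | None = None,
                       split: float = 0.25, seed: int = 0,
                       cv_folds: int = 5) -> tuple[list, dict]:
    """Per-dimension boosted regressors with a 75/25 train/validation split.

    Either ``params`` (a fixed hyperparameter set, e.g. :data:`PAPER_2024_XGB`)
    or ``grid`` (searched by ``cv_folds``-fold CV mean squared error on the
    training split) must be provided.  Returns (regressors, metrics) with
    validation R-squared and MAE per dimension.
    """
    latents = np.asarray(latents, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if grid is not None and not grid:
        raise ValueError("empty hyperparameter grid")
    xtr, xva, ytr, yva = train_test_split(latents, coords, test_size=split,
                                          random_state=seed)
    regs, metrics = [], {"r2": [], "mae": [], "best_params": []}
    for d in range(coords.shape[1]):
        if params is not None:
            best = dict(params)
        else:
            search = GridSearchCV(_make_xgb({}, seed), grid, cv=cv_folds,
                                  scoring="neg_mean_squared_error", n_jobs=1)
            search.fit(xtr, ytr[:, d])
            best = search.best_params_
        reg = _make_xgb(best, seed).fit(xtr, ytr[:, d])
        pred = reg.predict(xva)
        regs.append(reg)
        metrics["r2"].append(float(r2_score(yva[:, d], pred)))
        metrics["mae"].append(float(mean_absolute_error(yva[:, d], pred)))
        metrics["best_params"].append(best)
    return regs, metrics


def snap_to_tree(points: np.ndarray, tree) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonally project points onto the nearest embedded MST edge segment.

    Ties between equidistant edges break toward the lexicographically smaller
    (i, j) edge.  Returns (snapped points, distance moved).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    edges = tree.edges()
    Y = tree.Y
    a = Y[:, edges[:, 0]].T            # (E, dim)
    b = Y[:, edges[:, 1]].T
    ab = b - a
    denom = (ab * ab).sum(1)
    denom[denom == 0] = 1.0
    snapped = np.empty_like(pts)
    moved = np.empty(len(pts))
    for i, p in enumerate(pts):
        t = np.clip(((p - a) * ab).sum(1) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = np.linalg.norm(proj - p, axis=1)
        best = int(np.argmin(d))       # argmin = first minimum = smaller edge
        snapped[i] = proj[best]
        moved[i] = d[best]
    return snapped, moved


def fit_knn_assigner(coords: np.ndarray, phenogroups: np.ndarray,
                     k_range=range(1, 201), folds: int = 10, seed: int = 0
                     ) -> tuple[KNeighborsClassifier, int, pd.DataFrame]:
    """Choose K by cross-validated macro-F1 (ties toward smaller K).

    Returns (fitted classifier on all data, chosen K, per-K metric table).
    """
    coords = np.asarray(coords, dtype=float)
    phenogroups = np.asarray(phenogroups)
    ks = [k for k in k_range]
    max_train = len(coords) - len(coords) // folds
    if max(ks) > max_train:
        warnings.warn("k_range truncated to training-fold size")
        ks = [k for k in ks if k <= max_train]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(coords, phenogroups))
    rows = []
    for k in ks:
        f1s = []
        for tr, te in splits:
            clf = KNeighborsClassifier(n_neighbors=k).fit(coords[tr], phenogroups[tr])
            f1s.append(f1_score(phenogroups[te], clf.predict(coords[te]),
                                average="macro"))
        rows.append({"k": k, "macro_f1": float(np.mean(f1s))})
    table = pd.DataFrame(rows)
    best = table.sort_values(["macro_f1", "k"], ascending=[False, True]).iloc[0]
    k_opt = int(best["k"])
    clf = KNeighborsClassifier(n_neighbors=k_opt).fit(coords, phenogroups)
    return clf, k_opt, table


def build_projection_model(latents: np.ndarray, tree, phenogroups: np.ndarray,
                           norm: tuple, params: dict | None = None,
                           grid: dict | None = None, snap: bool = True,
                           knn_range=range(1, 51), knn_folds: int = 10,
                           seed: int = 0) -> ProjectionModel:
    """Train the full two-step projection (coordinate regression + KNN).

    ``latents`` are the derivation cohort's raw latent features; they are
    transformed with ``norm`` (the stored z-scoring) before training so the
    regressors see exactly the representation ``project_external`` feeds
    them.
    """
    from .ddrtree import apply_normalization

    if params is None and grid is None:
        params = dict(PAPER_2024_XGB)
    coords = tree.Z.T
    latents_n = apply_normalization(np.asarray(latents, dtype=float), *norm)
    regs, metrics = fit_dim_regressors(latents_n, coords, grid=grid,
                                       params=params, seed=seed)
    knn, k_opt, ktable = fit_knn_assigner(coords, phenogroups,
                                          k_range=knn_range, folds=knn_folds,
                                          seed=seed)
    metrics["knn_table"] = ktable
    return ProjectionModel(regs, norm, tree, knn, k_opt, snap, metrics)


def project_external(model: ProjectionModel, external_latents: np.ndarray,
                     already_normalised: bool = False) -> pd.DataFrame:
    """Project an external cohort onto the derivation tree.

    External latents are transformed with the derivation cohort's stored
    normalisation (never refit), regressed to coordinates, snapped to the
    tree if configured, and assigned phenogroups by the tuned KNN.
    Deterministic and identical whether records are passed in one batch or
    one at a time.
    """
    from .ddrtree import apply_normalization

    X = np.asarray(external_latents, dtype=float)
    if not already_normalised:
        mean, sd, keep = model.norm
        if X.shape[1] != len(np.asarray(mean)):
            raise ValueError(
                f"feature dimension {X.shape[1]} != derivation {len(np.asarray(mean))}")
        X = apply_normalization(X, mean, sd, keep)
    coords = np.column_stack([r.predict(X) for r in model.regressors]).astype(float)
    moved = np.zeros(len(coords))
    if model.snap:
        coords, moved = snap_to_tree(coords, model.tree)
    pheno = model.knn.predict(coords)
    return pd.DataFrame({"dim1": coords[:, 0], "dim2": coords[:, 1],
                         "snap_distance": moved, "phenogroup": pheno})


def nearest_point_similarity(embedding_a: np.ndarray, latents_a: np.ndarray,
                             embedding_b: np.ndarray, latents_b: np.ndarray
                             ) -> np.ndarray:
    """Spearman rho between latent vectors of nearest embedded point pairs.

    For each point in B, find its Euclidean nearest neighbour in A's
    embedding and correlate the two latent-feature vectors.
    """
    ea = np.asarray(embedding_a, dtype=float)
    eb = np.asarray(embedding_b, dtype=float)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("embeddings must be nonempty")
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=1).fit(ea)
    _, idx = nn.kneighbors(eb)
    rhos = np.array([spearmanr(latents_a[idx[i, 0]], latents_b[i]).statistic
                     for i in range(len(eb))])
    return rhos


def transition_matrices(pairs: pd.DataFrame, assignments: pd.Series | dict,
                        groups: list | None = None,
                        direction: str = "") -> tuple[pd.DataFrame, np.ndarray]:
    """Row-stochastic phenogroup transition matrix over rhythm-change pairs.

    Entry (g, h) is the proportion of pairs starting in phenogroup g whose
    second record is assigned to h; the diagonal is retention.  Returns
    (matrix as DataFrame, pair counts per starting group).
    """
    assign = dict(assignments) if not isinstance(assignments, dict) else assignments
    if groups is None:
        groups = sorted(set(assign.values()))
    G = len(groups)
    gi = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((G, G))
    if len(pairs) == 0:
        warnings.warn(f"no pairs for direction {direction!r}")
    for _, row in pairs.iterrows():
        g = assign[row["record_id_from"]]
        h = assign[row["record_id_to"]]
        counts[gi[g], gi[h]] += 1
    n_pairs = counts.sum(axis=1)
    mat = np.divide(counts, n_pairs[:, None],
                    out=np.zeros_like(counts), where=n_pairs[:, None] > 0)
    return pd.DataFrame(mat, index=groups, columns=groups), n_pairs
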