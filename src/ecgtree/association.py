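"""Characterisation of tree dimensions and phenogroups against phenotypes.

Global Moran's I spatial autocorrelation over the embedding, adjusted
linear/logistic/Cox regressions of outcomes on the (min-max normalised) tree
dimensions or on phenogroups with a fixed baseline group, prevalent-disease
and prior-treatment exclusion filters, generalised variance inflation
factors, and descriptive per-group tables (median/IQR + Kruskal-Wallis,
n (%) + chi-squared).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.neighbors import NearestNeighbors
import statsmodels.api as sm


@dataclass
class AssociationResult:
    term: str
    model_kind: str                  # linear | logistic | cox
    estimate: float                  # beta, OR, or HR
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    adjustment_set: tuple
    significant: bool = True

    def as_dict(self) -> dict:
        return {**self.__dict__, "adjustment_set": ",".join(self.adjustment_set)}


@dataclass
class SpatialStat:
    variable: str
    morans_i: float
    permutation_p: float
    n_permutations: int
    weight_spec: str


# --------------------------------------------------------------------------
# Moran's I


def knn_weights(coords: np.ndarray, k: int = 8) -> np.ndarray:
    """Row-standardised k-nearest-neighbour weight matrix over 2-D points."""
    coords = np.asarray(coords, dtype=float)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    n = len(coords)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            W[i, j] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    return W


def global_morans_i(values: np.ndarray, coords: np.ndarray | None = None,
                    weights: np.ndarray | None = None, k: int = 8,
                    n_perm: int = 999, seed: int = 0,
                    variable: str = "") -> SpatialStat:
    """Global Moran's I with a one-sided (greater) permutation test.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2;
    the permutation p-value shuffles values over locations with a fixed seed,
    p = (1 + #{I_perm >= I_obs}) / (n_perm + 1).
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if x.var() == 0:
        raise ValueError("zero-variance variable: Moran's I undefined")
    if weights is None:
        if coords is None:
            raise ValueError("need coords or an explicit weight matrix")
        W = knn_weights(coords, k=k)
        wspec = f"knn(k={k}, row-standardised)"
    else:
        W = np.asarray(weights, dtype=float)
        wspec = "explicit"
    n = x.size
    s0 = W.sum()

    def moran(v):
        z = v - v.mean()
        return (n / s0) * float(z @ W @ z) / float(z @ z)

    i_obs = moran(x)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if moran(rng.permutation(x)) >= i_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return SpatialStat(variable, float(i_obs), float(p), n_perm, wspec)


# --------------------------------------------------------------------------
# model fitting helpers


def minmax_dims(embedding: pd.DataFrame, dims=("dim1", "dim2")) -> pd.DataFrame:
    """Min-max normalise the tree dimensions (estimates are per unit of these)."""
    out = embedding.copy()
    for d in dims:
        lo, hi = out[d].min(), out[d].max()
        out[d] = (out[d] - lo) / (hi - lo if hi > lo else 1.0)
    return out


def _fit_one(df: pd.DataFrame, terms: list[str], outcome: str,
             model_kind: str, adjustment_set: tuple,
             duration_col: str | None = None) -> list[AssociationResult]:
    cols = terms + list(adjustment_set)
    use = df[cols + ([outcome] if model_kind != "cox" else
                     [duration_col, outcome])].dropna()
    n_used = len(use)
    Xd = use[cols].astype(float)
    const_cols = [c for c in Xd.columns if Xd[c].nunique() <= 1]
    if const_cols:
        raise ValueError(f"constant/singular design term(s): {const_cols}")

    results = []
    if model_kind == "cox":
        cph = CoxPHFitter()
        cph.fit(use[[duration_col, outcome] + cols], duration_col=duration_col,
                event_col=outcome)
        summ = cph.summary
        for t in terms:
            row = summ.loc[t]
            results.append(AssociationResult(
                t, "cox", float(np.exp(row["coef"])),
                float(np.exp(row["coef lower 95%"])),
                float(np.exp(row["coef upper 95%"])),
                float(row["p"]), n_used, adjustment_set,
                bool(row["p"] <= 0.05)))
        return results

    exog = sm.add_constant(Xd)
    y = use[outcome].astype(float)
    if model_kind == "logistic":
        if y.nunique() < 2:
            raise ValueError(f"outcome {outcome} has no variation (no events?)")
        fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
        transform = np.exp
    elif model_kind == "linear":
        fit = sm.OLS(y, exog).fit()
        transform = lambda v: v  # noqa: E731
    else:
        raise ValueError(f"unknown model kind {model_kind}")
    ci = fit.conf_int()
    for t in terms:
        results.append(AssociationResult(
            t, model_kind, float(transform(fit.params[t])),
            float(transform(ci.loc[t, 0])), float(transform(ci.loc[t, 1])),
            float(fit.pvalues[t]), n_used, adjustment_set,
            bool(fit.pvalues[t] <= 0.05)))
    return results


def regress_on_dims(df: pd.DataFrame, outcome: str, model_kind: str,
                    adjustment_set: tuple = (),
                    duration_col: str | None = None,
                    dims=("dim1", "dim2")) -> list[AssociationResult]:
    """One multivariable fit with both tree dimensions plus the adjustment set.

    Dimensions are min-max normalised inside, so estimates are per unit of
    normalised dimension.  Logistic fits report ORs, Cox fits HRs (Wald CIs).
    """
    d = minmax_dims(df, dims)
    return _fit_one(d, list(dims), outcome, model_kind, tuple(adjustment_set),
                    duration_col)


def regress_on_phenogroups(df: pd.DataFrame, outcome: str, model_kind: str,
                           baseline_group: int = 3,
                           adjustment_set: tuple = (),
                           duration_col: str | None = None,
                           group_col: str = "phenogroup"
                           ) -> list[AssociationResult]:
    """Phenogroup entered as categorical against a fixed baseline comparator.

    Raw estimates are always retained; ``significant`` flags p <= 0.05 (the
    convention used when non-significant estimates are displayed as null).
    """
    groups = sorted(df[group_col].dropna().unique())
    if baseline_group not in groups:
        raise ValueError(f"baseline group {baseline_group} absent")
    d = df.copy()
    terms = []
    for g in groups:
        if g == baseline_group:
            continue
        col = f"{group_col}_{g}"
        d[col] = (d[group_col] == g).astype(float)
        terms.append(col)
    return _fit_one(d, terms, outcome, model_kind, tuple(adjustment_set),
                    duration_col)


# --------------------------------------------------------------------------
# analysis filters


def incident_analysis_filter(cohort: pd.DataFrame, outcome: str
                             ) -> tuple[pd.DataFrame, int]:
    """Drop records with the outcome prevalent at/before the index ECG."""
    flag = f"prevalent_{outcome}"
    if flag not in cohort.columns:
        raise KeyError(f"no prevalence flag {flag}")
    keep = cohort[flag].fillna(0).astype(int) == 0
    return cohort[keep].copy(), int((~keep).sum())


def treatment_analysis_filter(cohort: pd.DataFrame, treatment: str
                              ) -> tuple[pd.DataFrame, int]:
    """Drop records whose treatment date precedes the index ECG."""
    tcol, timecol = treatment, f"{treatment}_time"
    prior = (cohort[tcol].fillna(0).astype(int) == 1) & \
            (cohort[timecol] < cohort["acquisition_time"])
    return cohort[~prior].copy(), int(prior.sum())


# --------------------------------------------------------------------------
# multicollinearity


def gvif(design: pd.DataFrame, term_grouping: dict[str, list[str]] | None = None
         ) -> pd.DataFrame:
    """Generalised VIF per term via the determinant-ratio formula.

    GVIF_j = det(R_jj) det(R_-j,-j) / det(R) on the correlation matrix R of
    the model columns (no intercept); scaled GVIF = GVIF^(1/(2 df)).  Terms
    with scaled GVIF above 3 are flagged.
    """
    X = design.astype(float)
    if term_grouping is None:
        term_grouping = {c: [c] for c in X.columns}
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("rank-deficient design (singular correlation matrix)")
    det_all = np.linalg.det(R)
    cols = list(X.columns)
    rows = []
    for term, members in term_grouping.items():
        j = [cols.index(m) for m in members]
        nj = [i for i in range(len(cols)) if i not in j]
        g = (np.linalg.det(R[np.ix_(j, j)]) *
             np.linalg.det(R[np.ix_(nj, nj)]) / det_all)
        df_term = len(j)
        scaled = g ** (1.0 / (2 * df_term))
        rows.append({"term": term, "df": df_term, "gvif": float(g),
                     "scaled_gvif": float(scaled), "flagged": scaled > 3.0})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# descriptive table


def descriptive_table(cohort: pd.DataFrame, group_col: str,
                      continuous: list[str], categorical: list[str]
                      ) -> pd.DataFrame:
    """Per-group median (IQR) / n (%) summaries with omnibus tests.

    Continuous variables: Kruskal-Wallis; categorical: Pearson chi-squared
    (flagged unreliable when an expected cell count is zero).
    """
    groups = sorted(cohort[group_col].dropna().unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    rows = []
    for var in continuous:
        vals = cohort[var]
        if vals.isna().all():
            warnings.warn(f"{var} all-missing; omitted")
            continue
        cells = {}
        samples = []
        for g in groups:
            v = cohort.loc[cohort[group_col] == g, var].dropna()
            samples.append(v)
            cells[g] = f"{v.median():.1f} ({v.quantile(.25):.1f}-{v.quantile(.75):.1f})"
        stat, p = stats.kruskal(*samples)
        rows.append({"variable": var, "type": "continuous", **cells,
                     "p": float(p), "test": "kruskal", "reliable": True})
    for var in categorical:
        vals = cohort[var]
        if vals.isna().all():
            warnings.warn(f"{var} all-missing; omitted")
            continue
        tab = pd.crosstab(cohort[group_col], cohort[var])
        cells = {}
        for g in groups:
            n1 = int(cohort.loc[cohort[group_col] == g, var].fillna(0).astype(float).gt(0).sum()) \
                if tab.shape[1] <= 2 else int(tab.loc[g].sum())
            tot = int((cohort[group_col] == g).sum())
            cells[g] = f"{n1} ({100 * n1 / max(tot, 1):.0f}%)"
        chi2, p, _, expected = stats.chi2_contingency(tab)
        rows.append({"variable": var, "type": "categorical", **cells,
                     "p": float(p), "test": "chi2",
                     "reliable": bool((expected > 0).all())})
    return pd.DataFrame(rows)
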