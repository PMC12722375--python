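"""Explainability: latent-feature associations and phenogroup ECG signatures.

For each phenogroup a single one-vs-rest multivariable logistic model over
all retained (standardised) latent units identifies the top-ranked units;
representative waveforms come from decoding per-group mean latent codes and
from latent traversals of the selected units.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .vae import decode_batch


def top_latents_per_phenogroup(latents: np.ndarray, phenogroups: np.ndarray,
                               top_n: int = 3, rank_by: str = "p"
                               ) -> pd.DataFrame:
    """Top latent units per phenogroup from one-vs-rest logistic models.

    ``latents`` (n x units) are standardised internally; every retained unit
    enters each model, so estimates are adjusted for all other features.
    Ranking is by ascending p-value (``rank_by='p'``) or by descending
    absolute log-odds (``rank_by='effect'``).  On separation the model is
    refit with an L2 penalty (flagged, no CIs).
    """
    X = np.asarray(latents, dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    phenogroups = np.asarray(phenogroups)
    n_units = X.shape[1]
    exog = sm.add_constant(X)
    rows = []
    for g in np.unique(phenogroups):
        y = (phenogroups == g).astype(float)
        penalised = False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, exog).fit(disp=0, maxiter=200)
            ok = (fit.mle_retvals.get("converged", True)
                  and np.isfinite(fit.bse).all() and (fit.bse < 50).all())
            if not ok:
                raise RuntimeError("separation / non-convergence")
            params, pvals = fit.params[1:], fit.pvalues[1:]
            ci = fit.conf_int()[1:]
        except Exception:
            fit = sm.Logit(y, exog).fit_regularized(
                alpha=1.0, L1_wt=0.0, disp=0, maxiter=500)
            params = np.asarray(fit.params)[1:]
            pvals = np.full(n_units, np.nan)
            ci = np.full((n_units, 2), np.nan)
            penalised = True
            warnings.warn(f"phenogroup {g}: separation; penalised refit")
        if rank_by == "p" and not penalised:
            order = np.argsort(pvals, kind="stable")
        else:
            order = np.argsort(-np.abs(params), kind="stable")
        for rank, u in enumerate(order[:top_n], start=1):
            rows.append({
                "phenogroup": g, "unit": int(u), "rank": rank,
                "aor": float(np.exp(params[u])),
                "ci_low": float(np.exp(ci[u][0])) if not penalised else np.nan,
                "ci_high": float(np.exp(ci[u][1])) if not penalised else np.nan,
                "p": float(pvals[u]) if not penalised else np.nan,
                "penalised": penalised,
            })
    return pd.DataFrame(rows)


def render_group_signatures(model, latents_full: np.ndarray,
                            phenogroups: np.ndarray) -> dict[int, np.ndarray]:
    """Decode the mean latent code of each phenogroup to an 8-lead beat.

    ``latents_full`` must be in the VAE's full latent space (all units).
    Empty groups are skipped with a warning.
    """
    sigs = {}
    phenogroups = np.asarray(phenogroups)
    for g in np.unique(phenogroups):
        members = latents_full[phenogroups == g]
        if len(members) == 0:
            warnings.warn(f"phenogroup {g} empty; skipped")
            continue
        sigs[int(g)] = decode_batch(model, members.mean(axis=0)[None])[0]
    return sigs
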