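"""End-to-end pipeline orchestration.

One config object holds every stage's parameters and seeds; ``run_pipeline``
executes simulate -> preprocess -> train-vae -> encode -> build-tree ->
consolidate -> associate -> explain (and optionally project), writing stage
artefacts plus a manifest of checksums.  Stages whose inputs and config are
unchanged are reloaded instead of recomputed, so deleting one intermediate
recomputes only the downstream stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import global_morans_i, regress_on_dims
from .ddrtree import DDRTreeParams, fit_ddrtree, normalize_features
from .explain import top_latents_per_phenogroup
from .phenogroups import consolidate_branches, compute_pseudotime, linkage_to_newick
from .preprocess import preprocess_collection
from .synthetic import default_specs, pipeline_view, simulate_cohort, truth_labels
from .vae import (VAEConfig, desk_config, encode_batch, paper_config,
                  reconstruction_fidelity, select_informative_units, train_vae)

log = logging.getLogger("ecgtree")


@dataclass
class PipelineConfig:
    preset: str = "desk"
    n_patients: int = 3000
    separation: str = "well-separated"
    seed_cohort: int = 11
    seed_vae: int = 12
    seed_tree: int = 13
    noise_sd: float = 0.02
    vae: VAEConfig = None
    tree: DDRTreeParams = None
    k_range: tuple = (2, 10)
    morans_n_perm: int = 199

    def __post_init__(self):
        if self.vae is None:
            maker = desk_config if self.preset == "desk" else paper_config
            self.vae = maker(seed=self.seed_vae)
        if self.tree is None:
            n_centroids = 400 if self.preset == "desk" else 2000
            self.tree = DDRTreeParams(n_centroids=n_centroids,
                                      seed=self.seed_tree)

    def digest(self) -> str:
        blob = json.dumps({**asdict_safe(self)}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg) -> dict:
    d = {}
    for k, v in cfg.__dict__.items():
        d[k] = asdict(v) if hasattr(v, "__dataclass_fields__") else v
    return d


def preset(name: str, **over) -> PipelineConfig:
    """Named presets: 'desk' (minutes on one CPU) and 'paper-2024'
    (full-width VAE, 2000 centroids)."""
    if name == "desk":
        return PipelineConfig(preset="desk", **over)
    if name == "paper-2024":
        return PipelineConfig(preset="paper-2024", **over)
    raise ValueError(f"unknown preset {name!r}")


STAGE_ORDER = ("simulate", "preprocess", "vae", "tree", "associate", "explain")


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 stages: tuple = STAGE_ORDER) -> dict:
    """Execute the pipeline, reusing stage outputs whose config is unchanged.

    ``stages`` selects a prefix of the stage order (downstream stages need
    the upstream artefacts).  Returns the manifest dict (also written to
    ``outdir/manifest.json``).
    """
    last = max(STAGE_ORDER.index(s) for s in stages)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mpath = out / "manifest.json"
    manifest = io.read_manifest(mpath) if mpath.exists() else {}
    digest = config.digest()
    if manifest.get("config_digest") != digest:
        manifest = {"config_digest": digest, "stages": {}}
    done = manifest["stages"]

    def fresh(stage, files):
        return (stage in done and done[stage]["config"] == digest and
                all((out / f).exists() for f in files))

    def record(stage, files, t0):
        done[stage] = {"config": digest, "seconds": round(time.time() - t0, 2),
                       "checksums": {f: io.file_checksum(out / f) for f in files}}
        io.write_manifest(mpath, manifest)

    # ---- simulate --------------------------------------------------------
    t0 = time.time()
    specs = default_specs(config.separation)
    if not fresh("simulate", ["cohort.csv", "truth.csv"]):
        log.info("simulate: %d patients", config.n_patients)
        cohort, _ = simulate_cohort(specs, config.n_patients,
                                    seed=config.seed_cohort)
        io.write_cohort(pipeline_view(cohort), out / "cohort.csv")
        truth_labels(cohort).to_csv(out / "truth.csv", index=False)
        record("simulate", ["cohort.csv", "truth.csv"], t0)
    cohort_vis = io.read_cohort(out / "cohort.csv")
    if last < 1:
        return manifest

    # ---- preprocess ------------------------------------------------------
    t0 = time.time()
    if not fresh("preprocess", ["beats.npz", "beats.index.csv"]):
        log.info("preprocess: rendering + median beats")
        cohort_full, ecgs = simulate_cohort(specs, config.n_patients,
                                            seed=config.seed_cohort)
        ecgs.noise_sd = config.noise_sd
        beats, ids, skipped = preprocess_collection(ecgs)
        io.write_beats(out / "beats", beats, ids)
        (out / "skipped.json").write_text(json.dumps(skipped))
        record("preprocess", ["beats.npz", "beats.index.csv"], t0)
    if last < 2:
        return manifest
    beats, beat_ids = io.read_beats(out / "beats")

    # ---- VAE -------------------------------------------------------------
    t0 = time.time()
    if not fresh("vae", ["latents.csv", "vae.npz"]):
        log.info("vae: training %d epochs", config.vae.epochs)
        pid_of = dict(zip(cohort_vis["record_id"], cohort_vis["patient_id"]))
        pids = np.array([pid_of[r] for r in beat_ids])
        model, trace, (tr, va, te) = train_vae(beats, pids, config.vae)
        model.save(out / "vae.npz")
        units = select_informative_units(model, beats[va],
                                         config.vae.info_threshold)
        mu, _ = encode_batch(model, beats)
        lat = pd.DataFrame(mu[:, units],
                           columns=[f"z{u}" for u in units])
        lat.insert(0, "record_id", beat_ids)
        lat.to_csv(out / "latents.csv", index=False)
        med_r, _ = reconstruction_fidelity(model, beats[te])
        (out / "vae_metrics.json").write_text(json.dumps({
            "median_test_pearson_r": med_r,
            "n_informative_units": int(len(units)),
            "final_train_recon_mae": trace.recon[-1]}))
        record("vae", ["latents.csv", "vae.npz"], t0)
    if last < 3:
        return manifest
    latents = pd.read_csv(out / "latents.csv")

    # ---- tree + phenogroups ---------------------------------------------
    t0 = time.time()
    if not fresh("tree", ["embedding.csv"]):
        log.info("tree: DDRTree with %d centroids", config.tree.n_centroids)
        zcols = [c for c in latents.columns if c.startswith("z")]
        Xn, mean, sd, keep = normalize_features(latents[zcols].to_numpy())
        tree = fit_ddrtree(Xn.T, config.tree)
        sol = consolidate_branches(tree, range(*config.k_range))
        pt = compute_pseudotime(tree)
        emb = pd.DataFrame({
            "record_id": latents["record_id"],
            "dim1": tree.Z[0], "dim2": tree.Z[1],
            "centroid": tree.R.argmax(axis=1),
            "sub_branch": sol.sub_branch_of_sample,
            "phenogroup": sol.phenogroup_of_sample,
            "pseudotime": pt.pseudotime_of_sample,
        })
        io.write_embedding(emb, out / "embedding.csv")
        np.savez(out / "tree.npz", W=tree.W, Z=tree.Z, Y=tree.Y, B=tree.B,
                 norm_mean=mean, norm_sd=sd, norm_keep=keep)
        pd.DataFrame(tree.edges(), columns=["i", "j"]).to_csv(
            out / "tree_edges.csv", index=False)
        if sol.linkage_record is not None:
            (out / "dendrogram.nwk").write_text(
                linkage_to_newick(sol.linkage_record))
        (out / "tree_metrics.json").write_text(json.dumps({
            "chosen_k": int(sol.chosen_k),
            "silhouette_by_k": {str(k): v for k, v in sol.silhouette_by_k.items()},
            "n_subbranches": int(sol.sub_branch_of_centroid.max() + 1)}))
        record("tree", ["embedding.csv"], t0)
    if last < 4:
        return manifest
    emb = io.read_embedding(out / "embedding.csv")

    if "associate" in stages:
        t0 = time.time()
        df = emb.merge(cohort_vis, on="record_id")
        stats = []
        for var in ("heart_rate", "age", "chads_vasc"):
            s = global_morans_i(df[var].to_numpy(),
                                df[["dim1", "dim2"]].to_numpy(),
                                n_perm=config.morans_n_perm,
                                seed=config.seed_tree, variable=var)
            stats.append(s.__dict__)
        assoc = []
        for res in regress_on_dims(df, "incident_event_hf", "cox",
                                   ("age", "heart_rate"),
                                   duration_col="incident_time_hf"):
            assoc.append(res.as_dict())
        pd.DataFrame(stats).to_csv(out / "morans.csv", index=False)
        pd.DataFrame(assoc).to_csv(out / "associations.csv", index=False)
        record("associate", ["morans.csv", "associations.csv"], t0)

    if "explain" in stages:
        t0 = time.time()
        zcols = [c for c in latents.columns if c.startswith("z")]
        top = top_latents_per_phenogroup(latents[zcols].to_numpy(),
                                         emb["phenogroup"].to_numpy())
        top.to_csv(out / "top_latents.csv", index=False)
        record("explain", ["top_latents.csv"], t0)

    return manifest
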