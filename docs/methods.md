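# Methods

`ecgtree` implements an unsupervised ECG phenotyping pipeline for atrial
fibrillation (AF) cohorts: 10-s 12-lead ECGs are reduced to R-aligned median
beats, compressed to disentangled latent features by an annealed β-VAE,
embedded as a two-dimensional principal tree (reversed graph embedding /
DDRTree), decomposed into sub-branches that are consolidated into
phenogroups, and characterised against clinical variables, echo measures and
survival outcomes.  Because the package ships no patient data, a synthetic
cohort generator provides inputs with the statistical structure every stage
assumes; this note documents both the science and what the synthetic results
do and do not establish.

## Synthetic cohort generator

**Waveform model.**  Each beat is a sum of Gaussians, one per wave (P, Q, R,
S, T), with per-lead amplitude patterns over the eight independent leads
(I, II, V1–V6); the remaining limb leads are derived by lead algebra
(III = II − I, aVR = −(I+II)/2, aVL = I − II/2, aVF = II − I/2) *before*
noise, so the algebra holds exactly on clean signals.  QRS offsets and
widths scale with the group's QRS duration; the R/S balance parameter tilts
precordial R against S amplitudes; T polarity/scale control repolarisation.
Sinus-rhythm records repeat the template at a fixed RR interval with a
P wave; AF records drop the P wave, draw RR intervals from a gamma
distribution (CV ≈ 0.29, always ≥ 0.15) and add a 4–9 Hz fibrillatory
baseline capped at 0.1 mV, which the median-beat operator largely removes.
White measurement noise (default 0.02 mV) is added last.

**Phenotype groups.**  Five groups lie on a branching continuum with the
"average paroxysmal" group 3 at the hub and four arms spanning **two**
morphology super-axes — a deliberate choice so that a two-dimensional tree
embedding can represent the full star:

| group | role | QRS ms | R/S | T | P mV | AF frac | HR bpm |
|---|---|---|---|---|---|---|---|
| 1 | persistent AF, tall-T end of repolarisation axis | 102 | 0.90 | +2.00 | 0.10 | 0.80 | 90 |
| 2 | AF + heart failure, wide-QRS end of remodelling axis | 145 | 0.45 | +0.95 | 0.11 | 0.85 | 100 |
| 3 | average paroxysmal AF (baseline, tree core) | 95 | 1.00 | +1.00 | 0.14 | 0.10 | 72 |
| 4 | low-risk paroxysmal, narrow-QRS end | 74 | 1.80 | +1.05 | 0.20 | 0.04 | 56 |
| 5 | high-risk paroxysmal, inverted-T end | 96 | 1.00 | −0.70 | 0.13 | 0.10 | 74 |

The arm displacements are deliberately near-balanced in length and spread
across exactly two axes: unbalanced or out-of-plane arms let the centroid
spanning tree shortcut between neighbouring arm tips instead of passing
through the hub, which merges planted groups.

Groups 1 and 5 sit at opposite ends of the repolarisation axis, so their top
associated latent features are shared with inverse signs.  Per-record
log-normal jitter (≈8 % on wave amplitudes, ≈5 % on QRS duration, mild
PR/QT-timing and per-lead gain variation) fills the continuum.  The `overlapping` preset shrinks every contrast 65 % toward the
cohort mean to emulate a blended cohort in which recovery is *not* expected.

Covariates (age, sex, CHA₂DS₂-VASc components with the standard 0–9
weighting), echo-like measures (LVEF, LVEDD, LA diameter, LAVi, diastolic
grade), prevalent-disease flags and rhythm-control treatment dates are drawn
with group-dependent shifts.  Outcomes (heart failure, stroke, death) are
exponential with per-group hazard multipliers against cohort baselines of
8×10⁻⁵, 4×10⁻⁵ and 1.2×10⁻⁴ events/day and administrative censoring at five
years; group 2 carries the planted HF multiplier 1.35.  Exponential hazards
with categorical multipliers make Cox recovery exact in expectation, which
is what the parameter-recovery suites exploit.

**What the generator does not emulate.**  Torso-geometry lead physics,
pacing and medication effects, beat-to-beat morphology dynamics beyond RR
irregularity, missing data, and measurement-protocol drift.  Passing
recovery tests therefore show the pipeline is *correct* under its stated
assumptions, not that it would find five groups in any hospital cohort.

## Pre-processing

Zero-phase (forward–backward) filtering: 4th-order Butterworth bandpass
0.5–100 Hz plus an IIR notch at the record's powerline frequency (Q = 30);
zero-phase filtering preserves R-peak latency.  Records are resampled to
400 Hz by polyphase filtering.  R peaks are detected on lead II (fallback:
lead of maximal squared-derivative energy) by a Pan–Tompkins-style
derivative–square–integrate detector with an adaptive threshold and 200 ms
refractory; records with fewer than three peaks are flagged unusable and
excluded, mirroring cohort-level quality control.  Median beats take the
pointwise median over beat windows of −300/+500 ms around each R peak
(320 samples at 400 Hz, R at index 120) after QRS cross-correlation
alignment on lead II within ±25 ms.  The window covers P through T at
physiological rates; the four derivable limb leads are dropped.

## Annealed β-VAE

Convolutional encoder: six convolution blocks (kernel 5, stride 1, ReLU)
with max-pooling after every second block, one final convolution, and a
fully connected layer producing the posterior mean and log-variance; the
decoder mirrors the encoder with nearest-neighbour upsampling.  The network
is implemented directly on numpy arrays with hand-written backpropagation
and Adam (lr 5×10⁻⁴, batch 128), which keeps the package dependency-light
and fully deterministic under a fixed seed.

Per batch the objective is

    L = (1/B) Σ_b Σ_elements |x − x̂|  +  β · | KL_batch − C(t) |

with β = 10, KL_batch the batch-mean total KL to the unit-Gaussian prior,
and capacity C(t) annealed linearly from 0 to `capacity_max` and then held
constant.  Both terms are *per sample* — the reconstruction error is summed
over the 8×320 beat elements — so the two gradients are commensurate;
averaging the reconstruction over elements instead makes the capacity term
dominate by three orders of magnitude and reliably collapses training.
Two further numerical choices matter:

- the posterior log-variance is clipped at 1.0 (just above the prior
  scale): the capacity pull-up gradient on log σ² is bistable, and without
  the cap any unit that drifts to σ² > 1 inflates until its noise swamps
  the decoder, which then permanently ignores the latent code;
- the capacity must be annealed quickly (defaults: first 10–50 % of
  epochs, a few hundred optimiser steps): slow schedules stretch the
  latent distribution for so long that the decoder settles into ignoring
  it — the same collapse by another route.

Splits are 85:5:10 grouped by patient id (leakage raises a hard error).
Informative units are those whose mean validation KL exceeds 0.1 nats,
ordered by descending KL; they define the feature set for all downstream
stages.  Reconstruction fidelity is the per-record Pearson correlation
between a held-out beat and its posterior-mean decode.  Latent traversals
decode a grid over [−3, 3] in steps of 0.5 (13 frames) on one unit with the
others fixed.

Named configurations: `desk_config` (latent 24, widths 12/16/24, 80
epochs, capacity 50 nats; about 5 minutes for ~3,000 beats on one CPU) and
`paper_config` (latent 256, widths 32/64/128, 200 epochs) matching the
full-scale architecture, which no test requires.

## Principal tree (DDRTree)

Latent features are z-scored (parameters stored and reused verbatim for
external cohorts).  The reversed-graph-embedding objective

    ‖X − WZ‖² + λ Σ_{(k,k')∈B} ‖y_k − y_k'‖²
             + γ Σ_i [ Σ_k r_ik ‖z_i − y_k‖² + σ Σ_k r_ik log r_ik ]

is minimised by alternating: a Euclidean MST over the centroids (Kruskal
with lexicographic (weight, i, j) tie-break for bit-reproducibility), a
row-softmax soft assignment at temperature σ, a closed-form linear solve
for the centroids Y, and an eigen-update for the orthonormal basis W and
sample coordinates Z.  Initialisation: Z from the top-2 principal
components (deterministic sign convention), Y from seeded k-means++.
Regulariser defaults follow the reference implementation — λ = 5·n_samples,
σ = 10⁻³, γ = 10, 20 iterations, tolerance 10⁻³ — with the centroid count
the only routinely changed knob.  The objective trace is recorded per
iteration and asserted non-increasing in every test fit; in the λ → 0,
σ → 0, centroids = samples limit the embedding provably reduces to PCA
scores, which the suite checks by Procrustes alignment.

The centroid count controls *sub-branch granularity*: with few centroids
the heavy smoothness prior collapses the tree to a handful of clean arms
and whole clusters share a maximal path, making finer phenogroups
unreachable.  The desk default is therefore 400 centroids for ~3,000
samples (≈13 %, close to the study-scale ratio), at which each planted arm
and the hub map to clean sub-branches; very large counts (≥1,000) produce
many more sub-branches but make silhouette-based model selection erratic
on filament-shaped embeddings.

## Phenogrouping

Sub-branches are maximal paths of the centroid MST between nodes of degree
≠ 2; branch nodes attach to the incident sub-branch of smallest id, empty
ids are densified away, and samples inherit the sub-branch of their nearest
centroid.  Each sub-branch is summarised by the min–max-normalised mean
coordinate of its centroids; summaries are clustered agglomeratively
(Euclidean, average linkage), the dendrogram is cut at k = 2…10, and the
mean silhouette over *sample* coordinates selects k (ties toward smaller
k).  Phenogroups are labelled 1..G by mean position for determinism.
Pseudotime is the geodesic distance along the MST from the tree centre (the
centroid minimising the maximum geodesic distance) plus the sample's
Euclidean offset to its nearest centroid.  Internal stability resamples the
cohort with replacement, refits tree + phenogroups, and summarises the
adjusted Rand index against the reference partition over the records present
in both (median and IQR over 20 resamples at desk scale); the resampling
design is this package's own protocol, so its ARI level is not comparable
to any externally reported value.

## Association analyses

Global Moran's I uses row-standardised k-nearest-neighbour weights (k = 8)
over the embedding coordinates and a one-sided permutation test with a
fixed seed (p = (1 + #{I_perm ≥ I_obs}) / (n_perm + 1)).  Outcome models
are multivariable: linear (OLS), logistic (Wald CIs, odds ratios) and Cox
(lifelines, Breslow ties, hazard ratios), with the tree dimensions entered
min–max-normalised or the phenogroup entered categorically against a fixed
baseline group (default 3).  Non-significant estimates (p > 0.05) are
flagged but raw values are always retained.  Incident analyses exclude
records with the outcome prevalent at the index ECG; treatment analyses
exclude records treated before the index ECG; both report exclusion counts.
Multicollinearity is assessed by generalised variance inflation factors via
the determinant-ratio formula on the model-column correlation matrix,
scaled as GVIF^(1/(2·df)) and flagged above 3.  Proportional-hazards
testing is deliberately omitted; hazard ratios are read as averages over
follow-up.  Missing covariates are handled by listwise deletion with the
count reported.

## External projection

A two-step supervised projection maps an external cohort onto a fitted
tree: per-dimension XGBoost regressors trained on the derivation cohort's
latent features (75/25 train/validation split; either a 5-fold CV grid
search or the shipped tuned configuration `PAPER_2024_XGB`: max depth 5,
subsample 0.6, colsample_bytree 0.6, learning rate 0.1, 200 trees), then an
optional snap of each predicted point to the nearest point on the embedded
centroid tree (orthogonal projection onto MST edge segments, ties to the
lexicographically smaller edge) — the snapping step is this package's
interpretation of an under-specified distance-correction step and can be
disabled — and finally a KNN phenogroup assigner whose K maximises
cross-validated macro-F1 (ties toward smaller K).  External latents are
always transformed with the derivation cohort's stored normalisation, never
refit, and projection is bitwise identical batch-by-batch or record-by-
record.  Rhythm-transition stability is quantified by row-stochastic
transition matrices over within-patient ECG pairs (≤ 30 days) whose rhythm
changed.

## Explainability

Per phenogroup, a single one-vs-rest multivariable logistic regression on
all retained (standardised) latent units ranks units by p-value (effect-
size ranking available); separation triggers an L2-penalised refit, flagged
and without CIs.  Group ECG signatures decode the per-group mean latent
code; 12-lead displays reconstruct the derived limb leads from I and II.

## Problem sizes and determinism

Desk-scale defaults used throughout the tests and the acceptance script:
3,000 patients (one ECG each), 400 Hz, 24-unit VAE at widths 12/16/24 for
80 epochs, 400 centroids, 5-fold/10-fold CV as stated.  Every stochastic
stage takes an explicit seed; the pipeline writes a manifest of per-stage
SHA-256 checksums, and identical configuration yields identical checksums.
Stages are cached: deleting an intermediate recomputes only downstream
stages.

## Known limitations

The waveform generator is morphological, not biophysical; rhythm, rate and
morphology are conditionally independent given the group beyond what the
template encodes.  Silhouette-based selection of the phenogroup count is
fragile when the embedding collapses clusters to filaments, and depends on
the centroid count as described.  The bootstrap stability protocol and the
tree-snapping step are documented interpretations of under-specified
procedures.  The from-scratch VAE trains on CPU at desk scale only; the
full-width configuration is provided but untested at scale.
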