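"""Synthetic AF cohort generator.

Produces 10-s 12-lead ECG records plus clinical/outcome tables with the
statistical structure the downstream tree pipeline assumes: a small number of
latent phenotype groups arranged along a morphological continuum, AF vs sinus
rhythm at acquisition (P wave present/absent, irregular RR), graded QRS
widening / T-wave inversion / heart-rate differences across groups, stroke-risk
covariates, echo-like continuous measures, and survival outcomes whose hazards
depend on group membership.

The waveform model is a sum of Gaussians per wave (P, Q, R, S, T) with
per-lead amplitude patterns; limb leads III/aVR/aVL/aVF are derived from I and
II by lead algebra so the algebra holds exactly on noiseless signals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LEADS_12 = ["I", "II", "III", "aVR", "aVL", "aVF",
            "V1", "V2", "V3", "V4", "V5", "V6"]
#: independent leads actually generated; the rest follow by lead algebra
LEADS_8 = ["I", "II", "V1", "V2", "V3", "V4", "V5", "V6"]

OUTCOMES = ["hf", "stroke", "death"]

#: default baseline hazards (events per day) for the simulated outcomes
BASELINE_HAZARDS = {"hf": 8e-5, "stroke": 4e-5, "death": 1.2e-4}

#: administrative censoring horizon, days (5-year follow-up)
CENSOR_TIME = 5 * 365.0


@dataclass(frozen=True)
class PhenotypeSpec:
    """Generative profile of one planted phenotype group.

    Morphology parameters control the ECG template; ``rhythm_mix`` is the
    probability a record is acquired in AF; ``hazard_multipliers`` are
    per-outcome relative hazards against the cohort baseline.
    """

    group_id: int
    prevalence: float
    p_wave_amplitude: float = 0.12      # mV, lead II
    qrs_duration: float = 90.0          # ms
    t_polarity: int = 1                 # +1 upright, -1 inverted precordials
    t_scale: float = 1.0                # T amplitude multiplier
    rs_ratio: float = 1.0               # R/S balance modifier (1 = neutral)
    heart_rate: tuple[float, float] = (70.0, 5.0)   # bpm mean, sd
    rhythm_mix: float = 0.2             # P(AF at acquisition)
    age_shift: float = 0.0              # years, additive
    male_frac: float = 0.55
    lvef_shift: float = 0.0             # percentage points, additive
    la_shift: float = 0.0               # mm, additive (LA diameter / size)
    comorbidity_scale: float = 1.0      # scales CHADS-VASc component odds
    hazard_multipliers: dict[str, float] = field(
        default_factory=lambda: {o: 1.0 for o in OUTCOMES})
    treatment_odds: dict[str, float] = field(
        default_factory=lambda: {"ablation": 0.10, "dccv": 0.10})

    def __post_init__(self) -> None:
        if not (60.0 <= self.qrs_duration <= 200.0):
            raise ValueError(f"qrs_duration {self.qrs_duration} outside [60, 200] ms")
        if not (0.0 <= self.rhythm_mix <= 1.0):
            raise ValueError("rhythm_mix must be a probability")
        if self.t_polarity not in (-1, 1):
            raise ValueError("t_polarity must be +1 or -1")
        if any(m <= 0 for m in self.hazard_multipliers.values()):
            raise ValueError("hazard multipliers must be > 0")


def default_specs(separation: str = "well-separated") -> list[PhenotypeSpec]:
    """The five shipped phenotype groups.

    ``well-separated`` places the groups in distinct regions of morphology
    space (QRS width, R/S balance, T polarity, P amplitude, rate) so that the
    planted partition is recoverable by the pipeline; ``overlapping`` shrinks
    every contrast toward the cohort mean to emulate a harder, blended cohort.

    The hub-and-arms layout puts the average paroxysmal group 3 at the tree
    core with four arms spanning two morphology super-axes, so the planted
    continuum branches as a star that a two-dimensional tree embedding can
    represent:
      QRS-remodelling axis -- group 2 (wide QRS, deep S, fast AF) against
        group 4 (narrow QRS, tall R, prominent P, slow sinus, low risk);
      repolarisation axis -- group 5 (inverted precordial T, excess
        mortality) against group 1 (tall peaked T with high AF burden);
    groups 1 and 5 sit at opposite ends of the same latent axis, so their
    top associated latent features are shared with inverse signs.
    """
    specs = [
        PhenotypeSpec(1, 0.20, p_wave_amplitude=0.10, qrs_duration=102.0,
                      t_polarity=1, t_scale=2.0, rs_ratio=0.90,
                      heart_rate=(90.0, 6.0), rhythm_mix=0.80, age_shift=2.0,
                      male_frac=0.65, lvef_shift=-2.0, la_shift=3.0,
                      comorbidity_scale=1.0,
                      hazard_multipliers={"hf": 1.15, "stroke": 1.10, "death": 1.10},
                      treatment_odds={"ablation": 0.13, "dccv": 0.22}),
        PhenotypeSpec(2, 0.18, p_wave_amplitude=0.11, qrs_duration=145.0,
                      t_polarity=1, t_scale=0.95, rs_ratio=0.45,
                      heart_rate=(100.0, 7.0), rhythm_mix=0.85, age_shift=4.0,
                      male_frac=0.60, lvef_shift=-12.0, la_shift=6.0,
                      comorbidity_scale=1.5,
                      hazard_multipliers={"hf": 1.35, "stroke": 1.15, "death": 1.25},
                      treatment_odds={"ablation": 0.08, "dccv": 0.20}),
        PhenotypeSpec(3, 0.27, p_wave_amplitude=0.14, qrs_duration=95.0,
                      t_polarity=1, t_scale=1.0, rs_ratio=1.0,
                      heart_rate=(72.0, 5.0), rhythm_mix=0.10, age_shift=0.0,
                      male_frac=0.55, lvef_shift=0.0, la_shift=0.0,
                      comorbidity_scale=1.0,
                      hazard_multipliers={"hf": 1.0, "stroke": 1.0, "death": 1.0},
                      treatment_odds={"ablation": 0.10, "dccv": 0.10}),
        PhenotypeSpec(4, 0.20, p_wave_amplitude=0.20, qrs_duration=74.0,
                      t_polarity=1, t_scale=1.05, rs_ratio=1.80,
                      heart_rate=(56.0, 4.0), rhythm_mix=0.04, age_shift=-9.0,
                      male_frac=0.50, lvef_shift=3.0, la_shift=-3.0,
                      comorbidity_scale=0.5,
                      hazard_multipliers={"hf": 0.80, "stroke": 0.85, "death": 0.80},
                      treatment_odds={"ablation": 0.17, "dccv": 0.06}),
        PhenotypeSpec(5, 0.15, p_wave_amplitude=0.13, qrs_duration=96.0,
                      t_polarity=-1, t_scale=0.70, rs_ratio=1.0,
                      heart_rate=(74.0, 5.0), rhythm_mix=0.10, age_shift=10.0,
                      male_frac=0.45, lvef_shift=-4.0, la_shift=5.0,
                      comorbidity_scale=1.8,
                      hazard_multipliers={"hf": 1.20, "stroke": 1.10, "death": 1.11},
                      treatment_odds={"ablation": 0.08, "dccv": 0.07}),
    ]
    if separation == "well-separated":
        return specs
    if separation == "overlapping":
        # shrink every morphological contrast 65% toward the cohort average
        mean_qrs = sum(s.qrs_duration * s.prevalence for s in specs)
        mean_hr = sum(s.heart_rate[0] * s.prevalence for s in specs)
        mean_p = sum(s.p_wave_amplitude * s.prevalence for s in specs)
        out = []
        for s in specs:
            shrink = lambda v, m: m + 0.35 * (v - m)  # noqa: E731
            out.append(replace(
                s,
                qrs_duration=shrink(s.qrs_duration, mean_qrs),
                heart_rate=(shrink(s.heart_rate[0], mean_hr), s.heart_rate[1] * 1.5),
                p_wave_amplitude=shrink(s.p_wave_amplitude, mean_p),
                rs_ratio=shrink(s.rs_ratio, 1.0),
                t_scale=shrink(s.t_scale, 1.0),
            ))
        return out
    raise ValueError(f"unknown separation preset {separation!r}")


# --------------------------------------------------------------------------
# CHA2DS2-VASc


def compute_chads_vasc(components: dict) -> int:
    """Standard CHA2DS2-VASc weighting from explicit components.

    Required keys: chf, hypertension, age (years), diabetes, stroke_tia,
    vascular_disease, sex ('M'/'F').  Missing keys raise (no imputation).
    """
    required = ["chf", "hypertension", "age", "diabetes", "stroke_tia",
                "vascular_disease", "sex"]
    missing = [k for k in required if k not in components or components[k] is None]
    if missing:
        raise ValueError(f"missing CHA2DS2-VASc components: {missing}")
    age = float(components["age"])
    score = 0
    score += int(bool(components["chf"]))
    score += int(bool(components["hypertension"]))
    score += 2 if age >= 75 else (1 if age >= 65 else 0)
    score += int(bool(components["diabetes"]))
    score += 2 * int(bool(components["stroke_tia"]))
    score += int(bool(components["vascular_disease"]))
    score += int(components["sex"] == "F")
    return score


# --------------------------------------------------------------------------
# ECG waveform template


def _wave_amplitudes(spec: PhenotypeSpec) -> dict[str, np.ndarray]:
    """Per-wave amplitude patterns (mV) over the 8 generated leads.

    Lead order: I, II, V1..V6.  Precordial R grows / S shrinks from V1 to V6;
    ``rs_ratio`` tilts the R/S balance; ``t_polarity`` flips the precordial T.
    """
    p = spec.p_wave_amplitude * np.array(
        [0.5, 1.0, 0.35, 0.25, 0.20, 0.25, 0.35, 0.40])
    r_base = np.array([0.70, 1.00, 0.20, 0.40, 0.70, 1.10, 1.20, 0.90])
    s_base = np.array([0.15, 0.20, 0.80, 1.00, 0.60, 0.35, 0.25, 0.15])
    q_base = np.array([0.06, 0.06, 0.00, 0.00, 0.02, 0.04, 0.06, 0.06])
    rs = spec.rs_ratio
    r = r_base * (2.0 * rs / (1.0 + rs))
    s = s_base * (2.0 / (1.0 + rs))
    t = spec.t_scale * np.array([0.25, 0.35, 0.15, 0.45, 0.50, 0.45, 0.35, 0.30])
    t[2:] *= spec.t_polarity
    return {"P": p, "Q": -q_base, "R": r, "S": -s, "T": t}


def _wave_timing(spec: PhenotypeSpec) -> dict[str, tuple[float, float]]:
    """(centre offset from R, Gaussian width), seconds. QRS scales with duration."""
    w = spec.qrs_duration / 1000.0 / 90.0 * 90.0  # seconds
    scale = spec.qrs_duration / 90.0
    return {
        "P": (-0.170, 0.022),
        "Q": (-0.030 * scale, 0.010 * scale),
        "R": (0.0, 0.016 * scale),
        "S": (0.030 * scale, 0.011 * scale),
        "T": (0.205 + 0.25 * w, 0.055),
    }


def beat_template(spec: PhenotypeSpec, t: np.ndarray,
                  p_wave: bool = True,
                  amp_jitter: np.ndarray | None = None,
                  timing_jitter: dict | None = None,
                  lead_gain: np.ndarray | None = None) -> np.ndarray:
    """Clean 8-lead beat evaluated at times ``t`` (seconds relative to R).

    Returns (8, len(t)) mV.  ``amp_jitter`` multiplies the five wave
    amplitude patterns (P,Q,R,S,T order); ``timing_jitter`` maps a wave to
    (centre shift s, width multiplier); ``lead_gain`` multiplies the eight
    independent leads — together they model per-record interval, width and
    electrode-placement variation that is independent of the phenotype.
    """
    amps = _wave_amplitudes(spec)
    timing = _wave_timing(spec)
    out = np.zeros((8, t.size))
    for i, wave in enumerate(["P", "Q", "R", "S", "T"]):
        if wave == "P" and not p_wave:
            continue
        mu, sd = timing[wave]
        if timing_jitter is not None and wave in timing_jitter:
            dmu, wmult = timing_jitter[wave]
            mu, sd = mu + dmu, sd * wmult
        shape = np.exp(-0.5 * ((t - mu) / sd) ** 2)
        a = amps[wave]
        if amp_jitter is not None:
            a = a * amp_jitter[i]
        out += a[:, None] * shape[None, :]
    if lead_gain is not None:
        out *= lead_gain[:, None]
    return out


def derive_limb_leads(eight: np.ndarray) -> np.ndarray:
    """Expand (8, n) independent leads [I,II,V1..V6] to the 12-lead set.

    III = II - I; aVR = -(I+II)/2; aVL = I - II/2; aVF = II - I/2.
    """
    lead_i, lead_ii = eight[0], eight[1]
    twelve = np.empty((12, eight.shape[1]), dtype=eight.dtype)
    twelve[0] = lead_i
    twelve[1] = lead_ii
    twelve[2] = lead_ii - lead_i
    twelve[3] = -(lead_i + lead_ii) / 2.0
    twelve[4] = lead_i - lead_ii / 2.0
    twelve[5] = lead_ii - lead_i / 2.0
    twelve[6:] = eight[2:]
    return twelve


def render_ecg(record: pd.Series | dict, spec: PhenotypeSpec,
               fs: float = 400.0, duration: float = 10.0,
               noise_sd: float = 0.02, seed: int | None = None,
               rng: np.random.Generator | None = None):
    """Render one 10-s 12-lead ECG for a cohort record.

    SR records repeat the template at a fixed RR; AF records drop the P wave,
    draw irregular RR intervals (coefficient of variation >= 0.15) and add a
    low-amplitude 4-9 Hz fibrillatory baseline.  Limb leads are derived by
    lead algebra *before* noise, so the algebra is exact at ``noise_sd=0``.

    Returns a :class:`~ecgtree.preprocess.RawECG`.
    """
    from .preprocess import RawECG

    if fs <= 0 or duration <= 0:
        raise ValueError("sampling rate and duration must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    rec = dict(record)
    rhythm = rec.get("rhythm", "SR")
    hr = float(rec.get("heart_rate", spec.heart_rate[0]))
    n = int(round(duration * fs))
    tgrid = np.arange(n) / fs

    # per-record morphology jitter: ~8% on wave amplitudes, ~5% on QRS
    # duration, turning the planted groups into a filled continuum
    amp_jitter = np.exp(rng.normal(0.0, 0.08, size=5))
    qrs_jit = float(np.clip(spec.qrs_duration * np.exp(rng.normal(0.0, 0.05)),
                            60.0, 200.0))
    spec = replace(spec, qrs_duration=qrs_jit)
    # mild phenotype-independent variation: PR/QT timing and per-lead gains
    # (electrode placement); kept small so it fills the continuum without
    # blurring the planted contrasts
    timing_jitter = {
        "P": (float(rng.normal(0.0, 0.005)), float(np.exp(rng.normal(0.0, 0.04)))),
        "T": (float(rng.normal(0.0, 0.005)), float(np.exp(rng.normal(0.0, 0.03)))),
    }
    lead_gain = np.exp(rng.normal(0.0, 0.02, size=8))

    rr_mean = 60.0 / hr
    if rhythm == "AF":
        # gamma RR intervals, CV = 1/sqrt(k); k=12 -> CV ~ 0.29
        k = 12.0
        rr = rng.gamma(k, rr_mean / k, size=int(duration / rr_mean * 2) + 8)
        rr = np.clip(rr, 0.35, 2.5)
        p_wave = False
    else:
        rr = np.full(int(duration / rr_mean) + 8, rr_mean)
        p_wave = True
    r_times = np.cumsum(rr) - rr[0] + 0.35  # first R at 0.35 s
    r_times = r_times[r_times < duration + 0.5]

    eight = np.zeros((8, n))
    for rt in r_times:
        rel = tgrid - rt
        mask = (rel > -0.45) & (rel < 0.65)
        if not mask.any():
            continue
        eight[:, mask] += beat_template(spec, rel[mask], p_wave=p_wave,
                                        amp_jitter=amp_jitter,
                                        timing_jitter=timing_jitter,
                                        lead_gain=lead_gain)

    if rhythm == "AF":
        # fibrillatory baseline: 4-9 Hz sinusoid mixture, total <= 0.1 mV
        fib = np.zeros(n)
        amps = rng.uniform(0.01, 0.03, size=4)
        amps *= min(1.0, 0.1 / amps.sum())
        for a in amps:
            f = rng.uniform(4.0, 9.0)
            phi = rng.uniform(0, 2 * np.pi)
            fib += a * np.sin(2 * np.pi * f * tgrid + phi)
        pattern = np.array([0.4, 0.8, 1.0, 0.8, 0.5, 0.4, 0.4, 0.4])
        eight += pattern[:, None] * fib[None, :]

    twelve = derive_limb_leads(eight)
    if noise_sd > 0:
        twelve = twelve + rng.normal(0.0, noise_sd, size=twelve.shape)

    return RawECG(signal=twelve, fs=fs, lead_names=list(LEADS_12),
                  powerline_hz=60, record_id=str(rec.get("record_id", "syn")),
                  rhythm=rhythm, meta={"r_times": r_times,
                                       "true_group": rec.get("true_group")})


class ECGCollection:
    """Lazy, deterministic sequence of rendered RawECG records.

    Record ``i`` is rendered from an RNG seeded by ``(seed, i)`` so rendering
    is bit-identical regardless of access order or batching.
    """

    def __init__(self, cohort: pd.DataFrame, specs: list[PhenotypeSpec],
                 seed: int, fs: float = 400.0, noise_sd: float = 0.02):
        self.cohort = cohort.reset_index(drop=True)
        self.specs = {s.group_id: s for s in specs}
        self.seed = seed
        self.fs = fs
        self.noise_sd = noise_sd

    def __len__(self) -> int:
        return len(self.cohort)

    def __getitem__(self, i: int):
        row = self.cohort.iloc[i]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, int(i)]))
        return render_ecg(row, self.specs[int(row["true_group"])],
                          fs=self.fs, noise_sd=self.noise_sd, rng=rng)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]


# --------------------------------------------------------------------------
# Cohort simulation


def _simulate_clinical(rng: np.random.Generator, spec: PhenotypeSpec) -> dict:
    age = float(np.clip(rng.normal(68.0 + spec.age_shift, 9.0), 30.0, 95.0))
    sex = "M" if rng.random() < spec.male_frac else "F"
    c = spec.comorbidity_scale
    comp = {
        "chf": rng.random() < min(0.9, 0.15 * c + (0.10 if spec.lvef_shift < -5 else 0.0)),
        "hypertension": rng.random() < min(0.9, 0.40 * c),
        "age": age,
        "diabetes": rng.random() < min(0.9, 0.18 * c),
        "stroke_tia": rng.random() < min(0.9, 0.08 * c),
        "vascular_disease": rng.random() < min(0.9, 0.15 * c),
        "sex": sex,
    }
    out = {
        "age": age, "sex": sex,
        "chf": int(comp["chf"]), "hypertension": int(comp["hypertension"]),
        "diabetes": int(comp["diabetes"]), "stroke_tia": int(comp["stroke_tia"]),
        "vascular_disease": int(comp["vascular_disease"]),
        "chads_vasc": compute_chads_vasc(comp),
        "lvef": float(np.clip(rng.normal(60.0 + spec.lvef_shift, 6.0), 15.0, 75.0)),
        "lvedd": float(np.clip(rng.normal(48.0 + 0.4 * spec.la_shift, 4.0), 35.0, 70.0)),
        "la_diameter": float(np.clip(rng.normal(38.0 + spec.la_shift, 4.0), 25.0, 60.0)),
        "lavi": float(np.clip(rng.normal(30.0 + 1.5 * spec.la_shift, 6.0), 12.0, 70.0)),
        "diastolic_grade": int(np.clip(rng.poisson(max(0.1, 0.5 * spec.comorbidity_scale)), 0, 3)),
    }
    return out


def simulate_outcomes(cohort: pd.DataFrame, specs: list[PhenotypeSpec],
                      baseline_hazards: dict[str, float] | None = None,
                      censor_time: float = CENSOR_TIME,
                      seed: int = 0,
                      extra_loghazard: dict[str, np.ndarray] | None = None
                      ) -> pd.DataFrame:
    """Draw exponential event times with per-group hazard multipliers.

    One row per cohort record; incident times are measured from the index ECG
    and administratively censored at ``censor_time``.  ``extra_loghazard``
    optionally adds a per-record log-hazard term per outcome (used to plant
    continuous position-dependent risks).
    """
    if baseline_hazards is None:
        baseline_hazards = BASELINE_HAZARDS
    if any(h <= 0 for h in baseline_hazards.values()):
        raise ValueError("baseline hazards must be > 0")
    if censor_time < 0:
        raise ValueError("censor_time must be >= 0")
    rng = np.random.default_rng(seed)
    spec_of = {s.group_id: s for s in specs}
    out = cohort.copy()
    groups = out["true_group"].to_numpy()
    n = len(out)
    for oc, h0 in baseline_hazards.items():
        mult = np.array([spec_of[g].hazard_multipliers.get(oc, 1.0) for g in groups])
        rate = h0 * mult
        if extra_loghazard is not None and oc in extra_loghazard:
            rate = rate * np.exp(np.asarray(extra_loghazard[oc], dtype=float))
        times = rng.exponential(1.0 / rate, size=n)
        event = times <= censor_time
        out[f"incident_time_{oc}"] = np.minimum(times, censor_time)
        out[f"incident_event_{oc}"] = event.astype(int)
    return out


def simulate_cohort(specs: list[PhenotypeSpec] | None = None,
                    n_patients: int = 3000,
                    ecgs_per_patient: int | str = 1,
                    seed: int = 0,
                    censor_time: float = CENSOR_TIME
                    ) -> tuple[pd.DataFrame, ECGCollection]:
    """Simulate a cohort table and its (lazily rendered) ECG collection.

    ``ecgs_per_patient``: 1 for the first-ECG-per-patient design, or
    ``"poisson2"`` to give each patient 1 + Poisson(1.5) records with 5-40 day
    gaps and per-record rhythm re-draws (enables rhythm-transition analyses).

    The ``true_group`` column is simulation truth; pipeline stages must not
    read it.  Identical (specs, seed) give bit-identical tables.
    """
    if specs is None:
        specs = default_specs()
    prev = np.array([s.prevalence for s in specs])
    if abs(prev.sum() - 1.0) > 1e-9:
        raise ValueError(f"prevalences sum to {prev.sum()}, not 1")
    if n_patients < len(specs):
        raise ValueError("need at least one patient per group")
    rng = np.random.default_rng(seed)
    spec_of = {s.group_id: s for s in specs}
    group_ids = np.array([s.group_id for s in specs])

    rows = []
    rid = 0
    for pid in range(n_patients):
        g = int(rng.choice(group_ids, p=prev))
        spec = spec_of[g]
        clin = _simulate_clinical(rng, spec)
        t0 = float(rng.uniform(0, 365.0))
        if ecgs_per_patient == 1:
            n_rec = 1
        elif ecgs_per_patient == "poisson2":
            n_rec = 1 + int(rng.poisson(1.5))
        else:
            n_rec = int(ecgs_per_patient)
        times = t0 + np.concatenate([[0.0], np.cumsum(rng.uniform(5.0, 40.0, size=n_rec - 1))])
        # treatments: dates drawn around the index ECG so some precede it
        treat = {}
        for tr in ("ablation", "dccv"):
            if rng.random() < spec.treatment_odds[tr]:
                treat[f"{tr}"] = 1
                treat[f"{tr}_time"] = t0 + float(rng.uniform(-180.0, 720.0))
            else:
                treat[f"{tr}"] = 0
                treat[f"{tr}_time"] = np.nan
        for j in range(n_rec):
            rhythm = "AF" if rng.random() < spec.rhythm_mix else "SR"
            hr = float(np.clip(rng.normal(*spec.heart_rate), 40.0, 160.0))
            prevalent = {f"prevalent_{oc}": int(rng.random() < p) for oc, p in {
                "hf": min(0.85, 0.12 * spec.comorbidity_scale + max(0.0, -spec.lvef_shift) * 0.015),
                "stroke": min(0.85, 0.07 * spec.comorbidity_scale),
                "death": 0.0,
            }.items()}
            rows.append({
                "patient_id": pid, "record_id": f"r{rid:06d}",
                "acquisition_time": float(times[j]), "rhythm": rhythm,
                "heart_rate": hr, "true_group": g,
                **clin, **prevalent, **treat,
            })
            rid += 1
    cohort = pd.DataFrame(rows)
    cohort = simulate_outcomes(cohort, specs, censor_time=censor_time,
                               seed=int(rng.integers(2**31)))
    return cohort, ECGCollection(cohort, specs, seed=seed)


def simulate_rhythm_pairs(cohort: pd.DataFrame, direction: str = "AF->SR",
                          max_gap: float = 30.0) -> pd.DataFrame:
    """Within-patient ordered record pairs whose rhythm changed.

    Returns a frame with record_id_from, record_id_to, gap (days).  Pairs are
    all ordered (earlier, later) record pairs of a patient with gap <= max_gap
    whose rhythms match the requested direction.
    """
    try:
        frm, to = direction.replace("→", "->").split("->")
    except ValueError:
        raise ValueError(f"direction {direction!r} must look like 'AF->SR'")
    pairs = []
    for _, grp in cohort.groupby("patient_id"):
        grp = grp.sort_values("acquisition_time")
        recs = grp[["record_id", "acquisition_time", "rhythm"]].to_numpy()
        for i in range(len(recs)):
            for j in range(i + 1, len(recs)):
                gap = recs[j][1] - recs[i][1]
                if gap > max_gap:
                    continue
                if recs[i][2] == frm and recs[j][2] == to:
                    pairs.append({"record_id_from": recs[i][0],
                                  "record_id_to": recs[j][0], "gap": gap})
    return pd.DataFrame(pairs, columns=["record_id_from", "record_id_to", "gap"])


def truth_labels(cohort: pd.DataFrame) -> pd.DataFrame:
    """Sidecar table of simulation truth, kept out of pipeline-visible data."""
    return cohort[["record_id", "true_group"]].copy()


def pipeline_view(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort table with simulation truth removed (what the pipeline may see)."""
    return cohort.drop(columns=["true_group"])
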