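"""ECG pre-processing: bandpass/notch filtering, resampling to 400 Hz,
R-peak detection, and fixed-length R-aligned 8-lead median beats.

The median-beat constructor here is a deliberately simple stand-in for a full
vectorcardiographic package: beats are windowed at [-300 ms, +500 ms] around
each detected R peak (320 samples at 400 Hz, R at index 120), re-aligned by
QRS cross-correlation on lead II, and reduced to the pointwise median per
lead.  Leads III/aVR/aVL/aVF are dropped (derivable from I and II).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig

from .synthetic import LEADS_12, LEADS_8

TARGET_FS = 400.0
BEAT_LEN = 320          # samples at 400 Hz: -300 ms .. +500 ms
R_INDEX = 120           # sample offset of the R peak inside the window
_EIGHT_IDX = [LEADS_12.index(l) for l in LEADS_8]


@dataclass
class RawECG:
    """One multi-lead ECG record with sampling metadata."""

    signal: np.ndarray              # leads x samples, mV
    fs: float
    lead_names: list[str]
    powerline_hz: int = 60
    record_id: str = ""
    rhythm: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.lead_names):
            raise ValueError("signal must be (n_leads, n_samples) matching lead_names")

    def lead(self, name: str) -> np.ndarray:
        return self.signal[self.lead_names.index(name)]


@dataclass
class MedianBeat:
    """R-aligned 8-lead median beat (leads I, II, V1-V6)."""

    beat: np.ndarray                # 8 x BEAT_LEN, mV
    fs: float = TARGET_FS
    r_index: int = R_INDEX
    n_beats_used: int = 0
    lead_names: list[str] = field(default_factory=lambda: list(LEADS_8))
    record_id: str = ""


class UnusableRecord(Exception):
    """Raised when a record cannot yield a usable median beat."""


def filter_ecg(raw: RawECG) -> RawECG:
    """Zero-phase 0.5-100 Hz bandpass plus powerline notch.

    Forward-backward filtering preserves R-peak latency.  Requires
    fs > 200 Hz so the 100 Hz passband edge is below Nyquist.
    """
    if raw.fs <= 200.0:
        raise ValueError(f"fs={raw.fs} too low for a 100 Hz passband edge")
    sos = sig.butter(4, [0.5, 100.0], btype="bandpass", fs=raw.fs, output="sos")
    y = sig.sosfiltfilt(sos, raw.signal, axis=1)
    b, a = sig.iirnotch(raw.powerline_hz, Q=30.0, fs=raw.fs)
    y = sig.filtfilt(b, a, y, axis=1)
    return RawECG(signal=y, fs=raw.fs, lead_names=list(raw.lead_names),
                  powerline_hz=raw.powerline_hz, record_id=raw.record_id,
                  rhythm=raw.rhythm, meta=dict(raw.meta))


def resample_ecg(raw: RawECG, target_fs: float = TARGET_FS) -> RawECG:
    """Polyphase resampling to ``target_fs``; identity if already there."""
    if raw.fs == target_fs:
        return raw
    from fractions import Fraction

    frac = Fraction(target_fs / raw.fs).limit_denominator(1000)
    y = sig.resample_poly(raw.signal, frac.numerator, frac.denominator, axis=1)
    return RawECG(signal=y, fs=target_fs, lead_names=list(raw.lead_names),
                  powerline_hz=raw.powerline_hz, record_id=raw.record_id,
                  rhythm=raw.rhythm, meta=dict(raw.meta))


def detect_r_peaks(raw: RawECG, detection_lead: str = "II",
                   refractory_ms: float = 200.0) -> np.ndarray:
    """Energy-based R detector on one lead (Pan-Tompkins-style).

    Differentiate, square, integrate over 90 ms, then pick peaks above an
    adaptive threshold with a >=200 ms refractory.  Falls back to the lead of
    maximal squared-derivative energy if the detection lead looks flat.
    Raises :class:`UnusableRecord` when fewer than 3 peaks are found.
    """
    fs = raw.fs
    x = raw.lead(detection_lead)
    if np.std(x) < 1e-6:
        energies = [np.sum(np.diff(ch) ** 2) for ch in raw.signal]
        x = raw.signal[int(np.argmax(energies))]
    d = np.gradient(x)
    e = d * d
    win = max(3, int(0.090 * fs))
    e = np.convolve(e, np.ones(win) / win, mode="same")
    if e.max() < 1e-10:
        raise UnusableRecord(f"{raw.record_id}: flatline")
    thr = 0.25 * np.percentile(e, 99)
    refractory = int(refractory_ms / 1000.0 * fs)
    idx, _ = sig.find_peaks(e, height=thr, distance=refractory)
    # refine each candidate to the local |x| maximum (R apex) within +-60 ms
    half = int(0.060 * fs)
    peaks = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(x[lo:hi]))))
    peaks = np.unique(peaks)
    # re-enforce refractory after refinement (keep earlier peak)
    kept: list[int] = []
    for p in peaks:
        if not kept or p - kept[-1] >= refractory:
            kept.append(int(p))
    if len(kept) < 3:
        raise UnusableRecord(f"{raw.record_id}: only {len(kept)} R peaks")
    return np.asarray(kept)


def build_median_beat(raw: RawECG, peaks: np.ndarray) -> MedianBeat:
    """Pointwise-median 8-lead beat from R-peak windows.

    Windows of [-300, +500] ms around each peak (dropped when they exceed the
    record); alignment refined by QRS cross-correlation on lead II within
    +-25 ms of the detected peak.  Needs >= 3 usable beats.
    """
    if raw.fs != TARGET_FS:
        raise ValueError("median beats are built at 400 Hz; resample first")
    x2 = raw.lead("II")
    pre, post = R_INDEX, BEAT_LEN - R_INDEX
    shift_max = int(0.025 * raw.fs)
    qrs_half = int(0.070 * raw.fs)

    # QRS alignment template: mean QRS over raw windows
    segs = []
    for p in peaks:
        if p - qrs_half < 0 or p + qrs_half >= x2.size:
            continue
        segs.append(x2[p - qrs_half:p + qrs_half + 1])
    if len(segs) < 3:
        raise UnusableRecord(f"{raw.record_id}: <3 in-bounds beats")
    template = np.mean(segs, axis=0)

    windows = []
    for p in peaks:
        best_s, best_c = 0, -np.inf
        for s in range(-shift_max, shift_max + 1):
            c = p + s
            if c - qrs_half < 0 or c + qrs_half >= x2.size:
                continue
            seg = x2[c - qrs_half:c + qrs_half + 1]
            corr = float(np.dot(seg, template))
            if corr > best_c:
                best_c, best_s = corr, s
        c = p + best_s
        if c - pre < 0 or c + post > raw.signal.shape[1]:
            continue
        windows.append(raw.signal[_EIGHT_IDX, c - pre:c + post])
    if len(windows) < 3:
        raise UnusableRecord(f"{raw.record_id}: <3 usable aligned beats")
    beat = np.median(np.stack(windows), axis=0)
    return MedianBeat(beat=beat, fs=raw.fs, r_index=R_INDEX,
                      n_beats_used=len(windows), record_id=raw.record_id)


def preprocess_record(raw: RawECG) -> MedianBeat:
    """filter -> resample to 400 Hz -> detect R -> median beat."""
    raw = filter_ecg(raw)
    raw = resample_ecg(raw)
    peaks = detect_r_peaks(raw)
    return build_median_beat(raw, peaks)


def preprocess_collection(records, progress: bool = False):
    """Run :func:`preprocess_record` over an iterable of RawECG.

    Returns (beats array records x 8 x 320, record_ids, skipped_ids).
    Unusable records are skipped and reported, mirroring cohort-level QC.
    """
    beats, ids, skipped = [], [], []
    for raw in records:
        try:
            mb = preprocess_record(raw)
        except UnusableRecord:
            skipped.append(raw.record_id)
            continue
        beats.append(mb.beat.astype(np.float32))
        ids.append(raw.record_id)
    if not beats:
        raise UnusableRecord("no usable records")
    return np.stack(beats), ids, skipped
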