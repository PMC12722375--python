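"""File I/O glue: CSV ECG records, cohort tables, beat containers, embeddings.

ECG CSV layout: a first comment line ``# fs=<Hz> powerline=<Hz>
record_id=<id> rhythm=<AF|SR>`` followed by a standard CSV with one column
per lead (named) and one row per sample, amplitudes in mV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import RawECG


def write_ecg_csv(raw: RawECG, path: str | Path) -> None:
    path = Path(path)
    header = (f"# fs={raw.fs:g} powerline={raw.powerline_hz} "
              f"record_id={raw.record_id} rhythm={raw.rhythm or 'NA'}\n")
    df = pd.DataFrame(raw.signal.T, columns=raw.lead_names)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.6f")


def read_ecg_csv(path: str | Path) -> RawECG:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=...' metadata line")
        meta = dict(tok.split("=", 1) for tok in first[1:].split())
        if "fs" not in meta:
            raise ValueError(f"{path}: metadata line lacks required key 'fs'")
        df = pd.read_csv(fh)
    rhythm = meta.get("rhythm")
    return RawECG(signal=df.to_numpy().T, fs=float(meta["fs"]),
                  lead_names=list(df.columns),
                  powerline_hz=int(float(meta.get("powerline", 60))),
                  record_id=meta.get("record_id", path.stem),
                  rhythm=None if rhythm == "NA" else rhythm)


def write_beats(path: str | Path, beats: np.ndarray, record_ids: list[str]) -> None:
    """Median-beat container: records x 8 x 320 array + record-id index table."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), beats=beats)
    pd.DataFrame({"row": range(len(record_ids)), "record_id": record_ids}
                 ).to_csv(path.with_suffix(".index.csv"), index=False)


def read_beats(path: str | Path) -> tuple[np.ndarray, list[str]]:
    path = Path(path)
    beats = np.load(path.with_suffix(".npz"))["beats"]
    idx = pd.read_csv(path.with_suffix(".index.csv"))
    return beats, idx["record_id"].tolist()


REQUIRED_COHORT_COLUMNS = ["patient_id", "record_id", "acquisition_time",
                           "rhythm", "age", "sex"]


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing required column(s): {missing}")
    return df


def write_embedding(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_embedding(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("record_id", "dim1", "dim2"):
        if col not in df.columns:
            raise ValueError(f"embedding file missing column {col!r}")
    return df


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def array_checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
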