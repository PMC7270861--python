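"""On-disk artifacts: waveform records, beat annotations, cohort tables.

A session recording is stored WFDB-style as a JSON header plus one raw
little-endian int16 ``.dat`` file per signal group, with a gain/offset
quantization documented in the header.  Beat annotations and the cohort
feature table are delimited text (CSV) with stable, documented columns.
"""
from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .types import BeatSeries, BEAT_FLAGS, PhaseLayout, Recording, ValidationError


class ParseError(ValidationError):
    """Malformed or inconsistent on-disk artifact."""


#: Default ADC gain: counts per signal unit.
ECG_GAIN = 1000.0
ACCEL_GAIN = 100.0

#: Stable cohort-table column set (one row per patient-session).
COHORT_COLUMNS = [
    "patient",
    "session",
    "group",
    "distance",
    "attendance",
    "compliance",
    "hr_rest",
    "hr_peak",
    "hr_rec1",
    "hr_rec2",
    "hr_rec3",
    "hr_rec4",
    "hr_rec5",
    "hr_peak_dist",
    "effort",
    "a_poly_walk",
    "b_poly_walk",
    "c_poly_walk",
    "r2_walk",
    "a_poly_rec",
    "b_poly_rec",
    "c_poly_rec",
    "r2_rec",
]


def _quantize(x: np.ndarray, gain: float) -> np.ndarray:
    q = np.round(np.asarray(x) * gain)
    if np.any(np.abs(q) > np.iinfo(np.int16).max):
        raise ValidationError("signal exceeds int16 range at this gain")
    return q.astype("<i2")


def write_recording(rec: Recording, prefix: Union[str, Path]) -> list:
    """Write header + signal files for one recording; returns paths written.

    Files: ``<prefix>.hea.json`` (metadata), ``<prefix>.ecg.dat`` and
    ``<prefix>.acc.dat`` (int16 little-endian counts; physical value =
    counts / gain).  Round-trips bit-exactly for integer-quantized samples.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ecg_q = _quantize(rec.ecg, ECG_GAIN)
    acc_q = _quantize(rec.accel, ACCEL_GAIN)
    header = {
        "format": "walkbeat-record-v1",
        "patient_id": rec.patient_id,
        "session": rec.session,
        "distance_m": rec.distance_m,
        "attendance": None if np.isnan(rec.attendance) else rec.attendance,
        "fs_ecg": rec.fs_ecg,
        "fs_accel": rec.fs_accel,
        "ecg_gain": ECG_GAIN,
        "accel_gain": ACCEL_GAIN,
        "n_ecg": int(ecg_q.size),
        "n_accel": int(acc_q.shape[0]),
        "phases": [
            ["rest", 0.0, rec.phases.rest_s],
            ["walk", rec.phases.rest_s, rec.phases.walk_s],
            ["recovery", rec.phases.rest_s + rec.phases.walk_s, rec.phases.recovery_s],
        ],
    }
    paths = [
        prefix.with_suffix(".hea.json"),
        prefix.with_suffix(".ecg.dat"),
        prefix.with_suffix(".acc.dat"),
    ]
    paths[0].write_text(json.dumps(header, indent=1, sort_keys=True))
    ecg_q.tofile(paths[1])
    acc_q.tofile(paths[2])
    return paths


def read_recording(prefix: Union[str, Path]) -> Recording:
    """Read a recording written by :func:`write_recording`, validating
    the header and signal-file sizes."""
    prefix = Path(prefix)
    hdr_path = prefix.with_suffix(".hea.json")
    if not hdr_path.exists():
        raise ParseError(f"missing header file {hdr_path}")
    try:
        hdr = json.loads(hdr_path.read_text())
    except json.JSONDecodeError as err:
        raise ParseError(f"{hdr_path}: invalid JSON ({err})") from err
    for field in ("fs_ecg", "fs_accel", "ecg_gain", "accel_gain", "n_ecg", "n_accel"):
        if field not in hdr:
            raise ParseError(f"{hdr_path}: missing field {field!r}")
        if not hdr[field] > 0:
            raise ParseError(f"{hdr_path}: field {field!r} must be > 0")
    ecg_path = prefix.with_suffix(".ecg.dat")
    acc_path = prefix.with_suffix(".acc.dat")
    for p, n_expect, per in ((ecg_path, hdr["n_ecg"], 1), (acc_path, hdr["n_accel"], 3)):
        if not p.exists():
            raise ParseError(f"missing signal file {p}")
        n_actual = os.path.getsize(p) // 2
        if n_actual != n_expect * per:
            raise ParseError(
                f"{p}: truncated or padded signal "
                f"(header says {n_expect * per} samples, file has {n_actual})"
            )
    ecg = np.fromfile(ecg_path, dtype="<i2").astype(float) / hdr["ecg_gain"]
    acc = (
        np.fromfile(acc_path, dtype="<i2").astype(float).reshape(-1, 3)
        / hdr["accel_gain"]
    )
    phases = {name: (onset, dur) for name, onset, dur in hdr["phases"]}
    layout = PhaseLayout(
        rest_s=phases["rest"][1],
        walk_s=phases["walk"][1],
        recovery_s=phases["recovery"][1],
    )
    att = hdr.get("attendance")
    return Recording(
        ecg=ecg,
        fs_ecg=hdr["fs_ecg"],
        accel=acc,
        fs_accel=hdr["fs_accel"],
        phases=layout,
        patient_id=hdr.get("patient_id", ""),
        session=int(hdr.get("session", 0)),
        distance_m=float(hdr.get("distance_m", 0.0)),
        attendance=float("nan") if att is None else float(att),
    )


def write_beats(beats: BeatSeries, path: Union[str, Path]) -> Path:
    """Beat annotations as CSV with columns ``time_s,flag``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": beats.times, "flag": beats.flags}).to_csv(
        path, index=False
    )
    return path


def read_beats(path: Union[str, Path]) -> BeatSeries:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"missing beats file {path}")
    df = pd.read_csv(path)
    if list(df.columns) != ["time_s", "flag"]:
        raise ParseError(f"{path}: expected columns time_s,flag, got {list(df.columns)}")
    if df.empty:
        return BeatSeries.from_times([])
    bad = set(df["flag"]) - set(BEAT_FLAGS)
    if bad:
        raise ParseError(f"{path}: unknown beat flags {sorted(bad)}")
    times = df["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ParseError(f"{path}: beat times not strictly increasing")
    return BeatSeries(times, df["flag"].to_numpy(dtype=object))


def write_cohort_table(table: pd.DataFrame, path: Union[str, Path]) -> Path:
    """Cohort feature table as CSV with the documented column set."""
    unknown = [c for c in table.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ValidationError(f"unexpected cohort columns: {unknown}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = table.reindex(columns=COHORT_COLUMNS)
    table.to_csv(path, index=False)
    return path


def read_cohort_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"missing cohort table {path}")
    df = pd.read_csv(path)
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS]
    if unknown:
        raise ParseError(f"{path}: unexpected columns {unknown}")
    dup = df.duplicated(subset=["patient", "session"])
    if dup.any():
        raise ParseError(f"{path}: duplicate (patient, session) rows")
    return df


def load_cohort_spec(path: Union[str, Path]):
    """Build a CohortSpec from a YAML config file."""
    from .simulate import CohortSpec, GroupProfile

    raw = yaml.safe_load(Path(path).read_text()) or {}
    profiles = []
    for pdata in raw.pop("profiles", []):
        pdata = dict(pdata)
        for key in ("walk_kinetics_by_session", "recovery_tau_by_session"):
            if key in pdata:
                pdata[key] = tuple(
                    tuple(v) if isinstance(v, (list, tuple)) else v
                    for v in pdata[key]
                )
        profiles.append(GroupProfile(**pdata))
    if "layout" in raw:
        raw["layout"] = PhaseLayout(**raw["layout"])
    try:
        return CohortSpec(profiles=tuple(profiles), **raw)
    except TypeError as err:
        raise ValidationError(f"invalid cohort spec: {err}") from err
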