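"""On-disk layout for sessions, feature tables and evaluation reports.

A session directory holds one wide CSV of streams plus a JSON metadata
sidecar::

    <session>/
      streams.csv   # one row per sample: L1_acc_x..L8_gyr_z, joint
                    # angles, pelvis_velocity
      meta.json     # subject, sampling rate, speed, lap intervals, runs

The write-read round trip is bit-identical for the metadata and within
float-print precision for the streams.  Feature tables are plain CSV
with the canonical feature names as header; evaluation reports are
JSON (structure) plus CSV (confusion matrix).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .types import JOINTS, LOCATION_CODES, EvalReport, SessionRecording

_AXES = ("x", "y", "z")
_FLOAT_FMT = "%.10g"


def _stream_columns(recording: SessionRecording) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    for code in LOCATION_CODES:
        if code not in recording.segment_streams:
            continue
        for kind, tag in (("accel", "acc"), ("angvel", "gyr")):
            arr = recording.segment_streams[code][kind]
            for a, axis in enumerate(_AXES):
                cols[f"{code}_{tag}_{axis}"] = arr[:, a]
    for joint in JOINTS:
        if joint in recording.joint_streams:
            cols[f"{joint}_angle"] = recording.joint_streams[joint]
    cols["pelvis_velocity"] = recording.pelvis_velocity
    return cols


def write_session(recording: SessionRecording, path) -> Path:
    """Write a validated session to ``path`` (a directory)."""
    recording.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(_stream_columns(recording))
    df.to_csv(path / "streams.csv", index=False, float_format=_FLOAT_FMT)
    meta = {
        "subject_id": recording.subject_id,
        "sampling_rate": recording.sampling_rate,
        "nominal_speed_kmh": recording.nominal_speed_kmh,
        "lap_starts": recording.lap_starts.tolist(),
        "lap_ends": recording.lap_ends.tolist(),
        "run_of_lap": list(recording.run_of_lap),
        "locations": sorted(recording.segment_streams,
                            key=LOCATION_CODES.index),
        "joints": [j for j in JOINTS if j in recording.joint_streams],
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))
    return path


def read_session(path) -> SessionRecording:
    """Read and validate a session written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValidationError(f"read_session: missing metadata {meta_path}")
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValidationError(f"read_session: malformed metadata: {exc}") from exc
    for code in meta.get("locations", []):
        if code not in LOCATION_CODES:
            raise ValidationError(f"read_session: unknown location code {code!r}")
    df = pd.read_csv(path / "streams.csv")

    def col(name: str) -> np.ndarray:
        if name not in df.columns:
            raise ValidationError(f"read_session: missing required stream {name!r}")
        return df[name].to_numpy(dtype=float)

    segment_streams = {}
    for code in meta.get("locations", []):
        segment_streams[code] = {
            "accel": np.stack([col(f"{code}_acc_{a}") for a in _AXES], axis=1),
            "angvel": np.stack([col(f"{code}_gyr_{a}") for a in _AXES], axis=1),
        }
    joint_streams = {j: col(f"{j}_angle") for j in meta.get("joints", [])}
    return SessionRecording(
        subject_id=meta["subject_id"],
        sampling_rate=float(meta["sampling_rate"]),
        segment_streams=segment_streams,
        joint_streams=joint_streams,
        pelvis_velocity=col("pelvis_velocity"),
        lap_starts=np.asarray(meta["lap_starts"], dtype=int),
        lap_ends=np.asarray(meta["lap_ends"], dtype=int),
        run_of_lap=meta["run_of_lap"],
        nominal_speed_kmh=float(meta["nominal_speed_kmh"]),
    )


def write_feature_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def report_to_dict(report: EvalReport) -> dict:
    return {
        "locations": sorted(report.configuration.locations),
        "category": report.configuration.category,
        "classes": list(report.classes),
        "accuracy_mean": report.accuracy_mean,
        "accuracy_std": report.accuracy_std,
        "per_class_metrics": {
            cls: {m: {"mean": mv, "std": sv} for m, (mv, sv) in d.items()}
            for cls, d in report.per_class_metrics.items()},
        "aggregate_confusion": report.aggregate_confusion.tolist(),
        "folds": [
            {"left_out_subject": f.left_out_subject,
             "confusion": f.confusion.tolist(),
             "accuracy": f.accuracy,
             "selected_features": [
                 {"rank": r + 1, "feature": name}
                 for r, name in enumerate(f.selected_features)]}
            for f in report.folds],
    }


def write_report(report: EvalReport, path) -> Path:
    """Write an evaluation report as JSON plus a confusion-matrix CSV."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "report.json").write_text(
        json.dumps(report_to_dict(report), indent=1))
    cm = pd.DataFrame(report.aggregate_confusion,
                      index=[f"true_{c}" for c in report.classes],
                      columns=[f"pred_{c}" for c in report.classes])
    cm.to_csv(path / "confusion.csv")
    ranks = pd.DataFrame([
        {"left_out_subject": f.left_out_subject, "rank": r + 1, "feature": name}
        for f in report.folds
        for r, name in enumerate(f.selected_features)])
    ranks.to_csv(path / "selected_features.csv", index=False)
    return path
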