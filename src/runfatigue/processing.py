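"""Stride-feature post-processing.

Three steps separate raw stride features from classifier input:

* a trailing moving average over one full lap (400 m) of running
  distance, which suppresses stride-to-stride noise and cancels the
  effect of the track's direction changes;
* per-subject z-score normalization, which removes between-subject
  offsets (running speed in particular shifts many features);
* fatigue-condition labeling per lap: laps 2-4 of the first
  constant-speed run are unfatigued, laps 8-10 mildly fatigued, laps 1-3
  of the final run (run directly after the fatiguing bout) heavily
  fatigued; every other lap is excluded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import FEATURE_NAMES
from .types import EXCLUDED

#: Non-feature columns carried through the pipeline.
META_COLUMNS = ("subject_id", "run_id", "lap", "lap_in_run", "distance_m",
                "label")


def assign_label(run_id: int, lap_in_run: int) -> str:
    """Fatigue condition of one lap (1-based lap number within its run)."""
    if run_id not in (1, 2, 3):
        raise ValidationError(f"run_id: {run_id} not in {{1, 2, 3}}")
    if lap_in_run < 1:
        raise ValidationError(f"lap_in_run: {lap_in_run} out of range")
    if run_id == 1:
        if lap_in_run > 10:
            raise ValidationError(f"lap_in_run: {lap_in_run} out of range for run 1")
        if 2 <= lap_in_run <= 4:
            return "no_fatigue"
        if 8 <= lap_in_run <= 10:
            return "mild_fatigue"
        return EXCLUDED
    if run_id == 3:
        if lap_in_run > 3:
            raise ValidationError(f"lap_in_run: {lap_in_run} out of range for run 3")
        return "heavy_fatigue"
    return EXCLUDED  # run 2 (the fatiguing bout) is never analysed


def lap_moving_average(features: pd.DataFrame, distances,
                       window_m: float = 400.0,
                       mode: str = "trailing") -> pd.DataFrame:
    """Moving average of stride features over one lap of distance.

    Row *i* becomes the mean of all rows whose distance lies in
    ``(d_i - window_m, d_i]`` (trailing/causal window; a centered window
    ``(d_i - w/2, d_i + w/2]`` is available via ``mode``).  Rows with
    less than one full window of history are dropped.  Distances must be
    non-decreasing and measured from the start of the run.
    """
    if window_m <= 0:
        raise ValidationError("window_m: must be > 0")
    if mode not in ("trailing", "centered"):
        raise ValidationError(f"mode: unknown mode {mode!r}")
    d = np.asarray(distances, dtype=float)
    if d.shape[0] != len(features):
        raise ValidationError("distances: length mismatch with features")
    if np.any(np.diff(d) < 0):
        raise ValidationError("distances: must be non-decreasing")
    if d.size == 0:
        return features.iloc[:0]

    if mode == "trailing":
        lo_edge, hi_edge = d - window_m, d
    else:
        lo_edge, hi_edge = d - window_m / 2.0, d + window_m / 2.0
    lo = np.searchsorted(d, lo_edge, side="right")
    hi = np.searchsorted(d, hi_edge, side="right")

    values = features.to_numpy(dtype=float)
    csum = np.vstack([np.zeros((1, values.shape[1])), np.nancumsum(values, axis=0)])
    counts = np.vstack([np.zeros((1, values.shape[1])),
                        np.cumsum(~np.isnan(values), axis=0)])
    sums = csum[hi] - csum[lo]
    ns = counts[hi] - counts[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(ns > 0, sums / ns, np.nan)

    keep = (d - d[0]) >= window_m
    if not keep.any():
        warnings.warn("total distance shorter than one smoothing window; "
                      "no rows retained", stacklevel=2)
    return pd.DataFrame(means[keep], columns=features.columns,
                        index=features.index[keep])


def zscore_per_subject(table: pd.DataFrame,
                       feature_cols: list[str] | None = None,
                       subject_col: str = "subject_id") -> pd.DataFrame:
    """Z-score every feature within each subject.

    Uses population statistics (``ddof=0``) over the subject's rows, so
    the transform is idempotent; zero-variance features map to 0.
    """
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c in set(FEATURE_NAMES)]
    sizes = table.groupby(subject_col).size()
    if (sizes < 2).any():
        bad = sizes[sizes < 2].index.tolist()
        raise ValidationError(f"zscore: subject(s) {bad} have fewer than 2 rows")
    out = table.copy()
    grouped = table.groupby(subject_col)[feature_cols]
    mean = grouped.transform("mean")
    std = grouped.transform(lambda s: s.std(ddof=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (table[feature_cols] - mean) / std
    out[feature_cols] = z.where(std > 0, 0.0)   # zero-variance features -> 0
    return out


def process_feature_table(table: pd.DataFrame, window_m: float = 400.0,
                          order: str = "smooth_then_zscore",
                          mode: str = "trailing",
                          stride_step: int = 1) -> pd.DataFrame:
    """Smooth, label and normalize a raw stride-feature table.

    ``table`` holds one row per stride with the catalogue features plus
    the meta columns ``subject_id``, ``run_id``, ``lap``, ``lap_in_run``
    and ``distance_m`` (distance from the start of the row's run).
    Smoothing windows never cross run boundaries.  Only labeled rows are
    returned; z-score parameters are computed per subject over those
    rows.  ``stride_step`` optionally thins the smoothed rows (heavily
    smoothed neighbours are nearly redundant).
    """
    if order not in ("smooth_then_zscore", "zscore_then_smooth"):
        raise ValidationError(f"order: unknown order {order!r}")
    feature_cols = [c for c in table.columns if c in set(FEATURE_NAMES)]
    if not feature_cols:
        raise ValidationError("table: no catalogue feature columns present")

    work = table
    if order == "zscore_then_smooth":
        work = zscore_per_subject(work, feature_cols)

    pieces = []
    for (_, _), group in work.groupby(["subject_id", "run_id"], sort=False):
        group = group.sort_values("distance_m")
        smoothed = lap_moving_average(group[feature_cols], group["distance_m"],
                                      window_m=window_m, mode=mode)
        meta = group.loc[smoothed.index, [c for c in META_COLUMNS
                                          if c in group.columns]]
        pieces.append(pd.concat([meta, smoothed], axis=1))
    out = pd.concat(pieces, axis=0) if pieces else work.iloc[:0]

    out = out.copy()
    out["label"] = [assign_label(int(r), int(l))
                    for r, l in zip(out["run_id"], out["lap_in_run"])]
    out = out[out["label"] != EXCLUDED]
    if stride_step > 1:
        pos = out.groupby(["subject_id", "run_id"], sort=False).cumcount()
        out = out[pos % stride_step == 0]
    out = out.reset_index(drop=True)
    if order == "smooth_then_zscore" and len(out):
        out = zscore_per_subject(out, feature_cols)
    return out
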