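"""Stride-level feature catalogue and extraction.

Each stride (one right gait cycle paired with the left cycle it contains)
yields 157 named features:

* 96 segment features — for each of the 8 IMU locations, 6 statistics
  (peak, mean, STD, IQR, skewness, kurtosis) of the acceleration
  magnitude and of the pitch angular velocity over the normalized cycle.
  The two peaks are biomechanical; the remaining ten are statistical.
* 22 joint-angle event extrema — per side: 3 for the ankle (initial
  contact, mid-stance, toe-off), 5 for the knee (adds mid-swing and
  end-swing), 3 for the hip (initial contact, toe-off, mid-swing).
* 30 joint-angle statistics — mean, STD, IQR, skewness, kurtosis per
  joint.
* 3 symmetry features — left minus right initial-contact extremum at
  each joint level.
* 2 shock attenuations — tibia-to-pelvis reduction of the peak
  acceleration magnitude, one per tibia, in percent.
* 4 spatiotemporal features — stride time and stride length for the
  left and the right gait cycle.

43 features are tagged biomechanical, 110 statistical, 4 spatiotemporal.
Canonical names follow a ``location_quantity_statistic`` /
``joint_side_event`` scheme and are stable across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError
from .types import CYCLE_POINTS, JOINT_SENSORS, JOINTS, LOCATION_CODES, GaitCycle

# ---------------------------------------------------------------------------
# catalogue
# ---------------------------------------------------------------------------

STATS: tuple[str, ...] = ("peak", "mean", "std", "iqr", "skew", "kurt")

#: Gait events per joint level; order fixes catalogue order.
JOINT_EVENTS: dict[str, tuple[str, ...]] = {
    "hip": ("ic", "toe_off", "mid_swing"),
    "knee": ("ic", "mid_stance", "toe_off", "mid_swing", "end_swing"),
    "ankle": ("ic", "mid_stance", "toe_off"),
}

#: Event windows as fractions of the normalized cycle (0 = initial contact).
EVENT_WINDOWS: dict[str, tuple[float, float]] = {
    "ic": (0.00, 0.05),
    "mid_stance": (0.05, 0.35),
    "toe_off": (0.30, 0.45),
    "mid_swing": (0.50, 0.75),
    "end_swing": (0.85, 1.00),
}

#: Whether the event extremum is a flexion maximum or an extension minimum.
EVENT_MODE: dict[tuple[str, str], str] = {
    ("hip", "ic"): "max",
    ("hip", "toe_off"): "min",
    ("hip", "mid_swing"): "max",
    ("knee", "ic"): "min",
    ("knee", "mid_stance"): "max",
    ("knee", "toe_off"): "min",
    ("knee", "mid_swing"): "max",
    ("knee", "end_swing"): "min",
    ("ankle", "ic"): "min",
    ("ankle", "mid_stance"): "max",
    ("ankle", "toe_off"): "min",
}


@dataclass(frozen=True)
class FeatureSpec:
    """One catalogue entry."""

    name: str
    family: str                  # biomechanical | statistical | spatiotemporal
    required_locations: frozenset[str]
    joint: str | None = None     # joint name for joint-derived features


def build_catalogue() -> list[FeatureSpec]:
    """Return the 157-entry feature catalogue in canonical order."""
    cat: list[FeatureSpec] = []
    # segment features: 8 locations x 2 quantities x 6 statistics
    for code in LOCATION_CODES:
        for quantity in ("accel", "angvel"):
            for stat in STATS:
                family = "biomechanical" if stat == "peak" else "statistical"
                cat.append(FeatureSpec(
                    name=f"{code}_{quantity}_{stat}",
                    family=family,
                    required_locations=frozenset({code}),
                ))
    # joint event extrema and statistics
    for joint in JOINTS:
        level, _, side = joint.partition("_")
        req = JOINT_SENSORS[joint]
        for event in JOINT_EVENTS[level]:
            cat.append(FeatureSpec(
                name=f"{level}_{side}_{event}",
                family="biomechanical",
                required_locations=req,
                joint=joint,
            ))
        for stat in STATS[1:]:   # mean, std, iqr, skew, kurt
            cat.append(FeatureSpec(
                name=f"{level}_{side}_{stat}",
                family="statistical",
                required_locations=req,
                joint=joint,
            ))
    # symmetry: left - right IC extremum per joint level
    for level in ("hip", "knee", "ankle"):
        req = JOINT_SENSORS[f"{level}_r"] | JOINT_SENSORS[f"{level}_l"]
        cat.append(FeatureSpec(
            name=f"{level}_symmetry_ic",
            family="biomechanical",
            required_locations=req,
        ))
    # shock attenuation tibia -> pelvis
    cat.append(FeatureSpec("shock_attenuation_r", "biomechanical",
                           frozenset({"L5", "L2"})))
    cat.append(FeatureSpec("shock_attenuation_l", "biomechanical",
                           frozenset({"L6", "L2"})))
    # spatiotemporal: attributed to the segmentation sources — the pelvis
    # (velocity) plus the sensors behind the right knee angle — so that
    # no single-IMU configuration exceeds its 12 segment features
    for name in ("stride_time_r", "stride_time_l",
                 "stride_length_r", "stride_length_l"):
        cat.append(FeatureSpec(name, "spatiotemporal",
                               frozenset({"L2", "L3", "L5"})))
    return cat


#: Module-level catalogue instance (the catalogue is static).
CATALOGUE: list[FeatureSpec] = build_catalogue()
FEATURE_NAMES: tuple[str, ...] = tuple(f.name for f in CATALOGUE)
CATALOGUE_INDEX: dict[str, int] = {n: i for i, n in enumerate(FEATURE_NAMES)}


def family_counts() -> dict[str, int]:
    counts: dict[str, int] = {}
    for f in CATALOGUE:
        counts[f.family] = counts.get(f.family, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def accel_magnitude(ax, ay, az) -> np.ndarray:
    """Root-sum-of-squares magnitude of a 3-axis acceleration."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not (ax.shape == ay.shape == az.shape):
        raise ValidationError("accel_magnitude: axis length mismatch")
    return np.sqrt(ax * ax + ay * ay + az * az)


def _curve_stats(curves: np.ndarray) -> dict[str, np.ndarray]:
    """Six summary statistics along the last axis of ``(n, 150)`` curves.

    Skewness (biased) and excess kurtosis are defined as 0 for
    zero-variance input to avoid NaN propagation on degenerate cycles.
    """
    q75, q25 = np.percentile(curves, [75, 25], axis=-1)
    sd = curves.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant curves
        skew = sstats.skew(curves, axis=-1, bias=True)
        kurt = sstats.kurtosis(curves, axis=-1, fisher=True, bias=True)
    degenerate = ~(sd > 0)
    skew = np.where(degenerate, 0.0, skew)
    kurt = np.where(degenerate, 0.0, kurt)
    return {
        "peak": curves.max(axis=-1),
        "mean": curves.mean(axis=-1),
        "std": sd,
        "iqr": q75 - q25,
        "skew": skew,
        "kurt": kurt,
    }


def segment_features(cycle: GaitCycle, location: str) -> dict[str, float]:
    """The 12 per-location features of one cycle (2 peaks + 10 statistics)."""
    out: dict[str, float] = {}
    for quantity, curve_name in (("accel", f"{location}_accel_mag"),
                                 ("angvel", f"{location}_angvel_pitch")):
        if curve_name not in cycle.curves:
            raise ValidationError(f"segment_features: missing curve {curve_name!r}")
        stats = _curve_stats(cycle.curves[curve_name][None, :])
        for stat in STATS:
            out[f"{location}_{quantity}_{stat}"] = float(stats[stat][0])
    return out


def shock_attenuation(tibia_accel_mag, pelvis_accel_mag) -> float:
    """Percent reduction of the peak acceleration from tibia to pelvis.

    ``SA = (1 - peak_pelvis / peak_tibia) * 100``; negative values mean
    amplification and are allowed.  A zero tibial peak yields NaN.
    """
    pt = float(np.max(np.asarray(tibia_accel_mag, dtype=float)))
    pp = float(np.max(np.asarray(pelvis_accel_mag, dtype=float)))
    if pt == 0.0:
        return float("nan")
    return (1.0 - pp / pt) * 100.0


def _event_slice(event: str, n: int = CYCLE_POINTS) -> slice:
    lo, hi = EVENT_WINDOWS[event]
    i0 = int(np.floor(lo * n))
    i1 = max(i0 + 1, int(np.ceil(hi * n)))
    return slice(i0, min(i1, n))


def joint_event_features(curve, joint_name: str) -> dict[str, float]:
    """Event extrema of one joint-angle cycle curve.

    Extrema are taken inside fixed percent-of-cycle windows; each event is
    a maximum (flexion-type) or a minimum (extension-type) per
    :data:`EVENT_MODE`.
    """
    level, _, side = joint_name.partition("_")
    if level not in JOINT_EVENTS or side not in ("r", "l"):
        raise ValidationError(f"joint_event_features: unknown joint {joint_name!r}")
    curve = np.asarray(curve, dtype=float)
    out: dict[str, float] = {}
    for event in JOINT_EVENTS[level]:
        window = curve[_event_slice(event, curve.shape[0])]
        mode = EVENT_MODE[(level, event)]
        out[f"{level}_{side}_{event}"] = float(window.max() if mode == "max"
                                               else window.min())
    return out


def symmetry_feature(left_peak: float, right_peak: float) -> float:
    """Left-minus-right difference of a per-side joint event feature."""
    return float(left_peak) - float(right_peak)


def spatiotemporal_features(stride_time_r: float, stride_time_l: float,
                            speed_mps: float) -> dict[str, float]:
    """Stride time (s) and stride length (m) per side.

    Stride length uses the controlled nominal running speed.
    """
    if speed_mps <= 0:
        raise ValidationError("spatiotemporal_features: speed must be > 0")
    return {
        "stride_time_r": float(stride_time_r),
        "stride_time_l": float(stride_time_l),
        "stride_length_r": float(stride_time_r) * speed_mps,
        "stride_length_l": float(stride_time_l) * speed_mps,
    }


# ---------------------------------------------------------------------------
# full extraction
# ---------------------------------------------------------------------------

#: Which cycle (by starting side) supplies each location's curves.  Axial
#: segments and right-side limbs come from the right cycle, left-side
#: limbs from the left cycle, so every signal is measured over the stride
#: of its own limb.
_SOURCE_SIDE: dict[str, str] = {
    "L1": "right", "L2": "right", "L3": "right", "L5": "right", "L7": "right",
    "L4": "left", "L6": "left", "L8": "left",
}


def _stack(cycles: list[GaitCycle], curve: str) -> np.ndarray | None:
    if not cycles or curve not in cycles[0].curves:
        return None
    return np.stack([c.curves[curve] for c in cycles])


def extract_table(right_cycles: list[GaitCycle], left_cycles: list[GaitCycle],
                  speed_mps: float, max_missing: float = 0.10) -> pd.DataFrame:
    """Extract the full 157-feature table for paired gait cycles.

    ``right_cycles[k]`` and ``left_cycles[k]`` must describe the same
    stride (the left cycle starting inside the right one).  Features whose
    source curves are absent are emitted as NaN; if more than
    ``max_missing`` of the catalogue is missing a :class:`ValidationError`
    is raised.
    """
    if len(right_cycles) != len(left_cycles):
        raise ValidationError("extract_table: unpaired cycles")
    n = len(right_cycles)
    if n == 0:
        return pd.DataFrame(columns=list(FEATURE_NAMES))
    if speed_mps <= 0:
        raise ValidationError("extract_table: speed must be > 0")
    cycles_of = {"right": right_cycles, "left": left_cycles}
    cols: dict[str, np.ndarray] = {}

    # segment statistics
    for code in LOCATION_CODES:
        source = cycles_of[_SOURCE_SIDE[code]]
        for quantity, curve in (("accel", f"{code}_accel_mag"),
                                ("angvel", f"{code}_angvel_pitch")):
            arr = _stack(source, curve)
            stats = _curve_stats(arr) if arr is not None else None
            for stat in STATS:
                name = f"{code}_{quantity}_{stat}"
                cols[name] = np.full(n, np.nan) if stats is None else stats[stat]

    # joint events + statistics
    ic_event: dict[str, np.ndarray] = {}
    for joint in JOINTS:
        level, _, side = joint.partition("_")
        source = cycles_of["right" if side == "r" else "left"]
        arr = _stack(source, f"{joint}_angle")
        if arr is None:
            for event in JOINT_EVENTS[level]:
                cols[f"{level}_{side}_{event}"] = np.full(n, np.nan)
            for stat in STATS[1:]:
                cols[f"{level}_{side}_{stat}"] = np.full(n, np.nan)
            ic_event[joint] = np.full(n, np.nan)
            continue
        for event in JOINT_EVENTS[level]:
            window = arr[:, _event_slice(event)]
            mode = EVENT_MODE[(level, event)]
            vals = window.max(axis=1) if mode == "max" else window.min(axis=1)
            cols[f"{level}_{side}_{event}"] = vals
            if event == "ic":
                ic_event[joint] = vals
        stats = _curve_stats(arr)
        for stat in STATS[1:]:
            cols[f"{level}_{side}_{stat}"] = stats[stat]

    # symmetry (left - right IC extremum)
    for level in ("hip", "knee", "ankle"):
        cols[f"{level}_symmetry_ic"] = ic_event[f"{level}_l"] - ic_event[f"{level}_r"]

    # shock attenuation within each tibia's own cycle
    for name, tibia, side in (("shock_attenuation_r", "L5", "right"),
                              ("shock_attenuation_l", "L6", "left")):
        t = _stack(cycles_of[side], f"{tibia}_accel_mag")
        p = _stack(cycles_of[side], "L2_accel_mag")
        if t is None or p is None:
            cols[name] = np.full(n, np.nan)
        else:
            pt = t.max(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                sa = (1.0 - p.max(axis=1) / pt) * 100.0
            cols[name] = np.where(pt == 0.0, np.nan, sa)

    # spatiotemporal
    st_r = np.array([c.stride_time for c in right_cycles])
    st_l = np.array([c.stride_time for c in left_cycles])
    cols["stride_time_r"] = st_r
    cols["stride_time_l"] = st_l
    cols["stride_length_r"] = st_r * speed_mps
    cols["stride_length_l"] = st_l * speed_mps

    table = pd.DataFrame({name: cols[name] for name in FEATURE_NAMES})
    missing_frac = table.isna().all(axis=0).mean()
    if missing_frac > max_missing:
        raise ValidationError(
            f"extract_table: {missing_frac:.0%} of features missing source curves"
        )
    return table


def extract_feature_vector(right_cycle: GaitCycle, left_cycle: GaitCycle,
                           speed_mps: float) -> dict[str, float]:
    """157 named feature values for one stride (cycle pair)."""
    table = extract_table([right_cycle], [left_cycle], speed_mps)
    return {name: float(table.at[0, name]) for name in FEATURE_NAMES}
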