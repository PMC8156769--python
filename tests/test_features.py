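"""Feature catalogue and extraction, checked against a brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from runfatigue.errors import ValidationError
from runfatigue.features import (CATALOGUE, EVENT_MODE, EVENT_WINDOWS,
                                 FEATURE_NAMES, JOINT_EVENTS, accel_magnitude,
                                 extract_feature_vector, extract_table,
                                 family_counts, joint_event_features,
                                 segment_features, shock_attenuation,
                                 spatiotemporal_features, symmetry_feature)
from runfatigue.types import CYCLE_POINTS, GaitCycle


# ---------------------------------------------------------------------------
# independent brute-force oracle (plain Python, no shared code paths)
# ---------------------------------------------------------------------------

def _o_mean(x):
    return sum(x) / len(x)


def _o_std(x):
    m = _o_mean(x)
    return math.sqrt(sum((v - m) ** 2 for v in x) / (len(x) - 1))


def _o_percentile(x, q):
    s = sorted(x)
    h = (len(s) - 1) * q / 100.0
    lo = int(math.floor(h))
    if lo + 1 >= len(s):
        return s[-1]
    return s[lo] + (s[lo + 1] - s[lo]) * (h - lo)


def _o_skew(x):
    m = _o_mean(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m3 = sum((v - m) ** 3 for v in x) / len(x)
    return 0.0 if m2 == 0 else m3 / m2 ** 1.5


def _o_kurt(x):
    m = _o_mean(x)
    m2 = sum((v - m) ** 2 for v in x) / len(x)
    m4 = sum((v - m) ** 4 for v in x) / len(x)
    return 0.0 if m2 == 0 else m4 / m2 ** 2 - 3.0


def _o_stats(x):
    return {"peak": max(x), "mean": _o_mean(x), "std": _o_std(x),
            "iqr": _o_percentile(x, 75) - _o_percentile(x, 25),
            "skew": _o_skew(x), "kurt": _o_kurt(x)}


def _o_event(curve, event, mode):
    lo, hi = EVENT_WINDOWS[event]
    i0 = int(math.floor(lo * len(curve)))
    i1 = max(i0 + 1, int(math.ceil(hi * len(curve))))
    window = list(curve[i0:min(i1, len(curve))])
    return max(window) if mode == "max" else min(window)


def oracle_feature_vector(right, left, speed_mps):
    """Brute-force recoding of the full 157-feature extraction."""
    side_of = {"L1": right, "L2": right, "L3": right, "L5": right,
               "L7": right, "L4": left, "L6": left, "L8": left}
    out = {}
    for code, cyc in side_of.items():
        for quantity, curve in (("accel", f"{code}_accel_mag"),
                                ("angvel", f"{code}_angvel_pitch")):
            for stat, val in _o_stats(list(cyc.curves[curve])).items():
                out[f"{code}_{quantity}_{stat}"] = val
    for joint_side, cyc in (("r", right), ("l", left)):
        for level in ("hip", "knee", "ankle"):
            curve = cyc.curves[f"{level}_{joint_side}_angle"]
            for event in JOINT_EVENTS[level]:
                out[f"{level}_{joint_side}_{event}"] = _o_event(
                    curve, event, EVENT_MODE[(level, event)])
            stats = _o_stats(list(curve))
            for stat in ("mean", "std", "iqr", "skew", "kurt"):
                out[f"{level}_{joint_side}_{stat}"] = stats[stat]
    for level in ("hip", "knee", "ankle"):
        out[f"{level}_symmetry_ic"] = (out[f"{level}_l_ic"]
                                       - out[f"{level}_r_ic"])
    for suffix, cyc, tibia in (("r", right, "L5"), ("l", left, "L6")):
        pt = max(cyc.curves[f"{tibia}_accel_mag"])
        pp = max(cyc.curves["L2_accel_mag"])
        out[f"shock_attenuation_{suffix}"] = (1 - pp / pt) * 100.0
    out["stride_time_r"] = right.stride_time
    out["stride_time_l"] = left.stride_time
    out["stride_length_r"] = right.stride_time * speed_mps
    out["stride_length_l"] = left.stride_time * speed_mps
    return out


def test_extraction_matches_brute_force_oracle(random_cycle_pairs):
    pairs, speed = random_cycle_pairs
    for right, left in pairs:
        got = extract_feature_vector(right, left, speed)
        want = oracle_feature_vector(right, left, speed)
        assert set(got) == set(want)
        for name in want:
            assert got[name] == pytest.approx(want[name], abs=1e-9), name


# ---------------------------------------------------------------------------
# catalogue structure
# ---------------------------------------------------------------------------

def test_catalogue_arithmetic():
    assert len(FEATURE_NAMES) == 157
    assert len(set(FEATURE_NAMES)) == 157
    assert family_counts() == {"biomechanical": 43, "statistical": 110,
                               "spatiotemporal": 4}


def test_catalogue_component_counts():
    segment = [f for f in CATALOGUE if f.name.startswith("L")
               and "shock" not in f.name]
    assert len(segment) == 96          # 8 locations x 12
    events = [f for f in CATALOGUE if f.family == "biomechanical"
              and f.joint is not None]
    assert len(events) == 22           # knee 5x2, ankle 3x2, hip 3x2
    assert sum("symmetry" in f.name for f in CATALOGUE) == 3
    assert sum("shock" in f.name for f in CATALOGUE) == 2
    joint_stats = [f for f in CATALOGUE if f.family == "statistical"
                   and f.joint is not None]
    assert len(joint_stats) == 30


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("axes,expected", [
    ((3.0, 4.0, 0.0), 5.0),
    ((0.0, 0.0, 0.0), 0.0),
    ((1.0, 1.0, 1.0), math.sqrt(3)),
])
def test_accel_magnitude(axes, expected):
    out = accel_magnitude(*[np.array([a]) for a in axes])
    assert out[0] == pytest.approx(expected, abs=1e-7)


def _cycle_with(curves):
    base = {name: np.zeros(CYCLE_POINTS) for name in curves}
    for name, val in curves.items():
        base[name] = np.asarray(val, dtype=float)
    return GaitCycle(side="right", start_index=0, end_index=100,
                     stride_time=0.75, stride_distance=2.5, curves=base)


def test_segment_features_constant_curve():
    c = _cycle_with({"L6_accel_mag": np.full(CYCLE_POINTS, 7.0),
                     "L6_angvel_pitch": np.full(CYCLE_POINTS, 7.0)})
    out = segment_features(c, "L6")
    assert len(out) == 12
    for quantity in ("accel", "angvel"):
        assert out[f"L6_{quantity}_peak"] == 7.0
        assert out[f"L6_{quantity}_mean"] == 7.0
        for stat in ("std", "iqr", "skew", "kurt"):
            assert out[f"L6_{quantity}_{stat}"] == 0.0


def test_segment_statistics_recover_normal_moments():
    """Averaged over many cycles of N(0,1) noise: mean~0, STD~1, IQR~1.349."""
    rng = np.random.default_rng(1)
    vals = {"mean": [], "std": [], "iqr": []}
    for _ in range(300):
        x = rng.standard_normal(CYCLE_POINTS)
        c = _cycle_with({"L6_accel_mag": x, "L6_angvel_pitch": x})
        out = segment_features(c, "L6")
        for k in vals:
            vals[k].append(out[f"L6_accel_{k}"])
    assert np.mean(vals["mean"]) == pytest.approx(0.0, abs=0.02)
    assert np.mean(vals["std"]) == pytest.approx(1.0, abs=0.02)
    assert np.mean(vals["iqr"]) == pytest.approx(1.349, abs=0.03)


@pytest.mark.parametrize("pt,pp,expected", [
    (10.0, 10.0, 0.0),
    (10.0, 5.0, 50.0),
    (10.0, 12.0, -20.0),
])
def test_shock_attenuation(pt, pp, expected):
    tib = np.zeros(CYCLE_POINTS); tib[3] = pt
    pel = np.zeros(CYCLE_POINTS); pel[5] = pp
    assert shock_attenuation(tib, pel) == pytest.approx(expected)


def test_shock_attenuation_zero_tibial_peak_is_missing():
    assert math.isnan(shock_attenuation(np.zeros(10), np.ones(10)))


def test_joint_event_counts():
    knee = joint_event_features(np.zeros(CYCLE_POINTS), "knee_r")
    ankle = joint_event_features(np.zeros(CYCLE_POINTS), "ankle_l")
    hip = joint_event_features(np.zeros(CYCLE_POINTS), "hip_r")
    assert len(knee) == 5 and len(ankle) == 3 and len(hip) == 3
    assert 2 * (5 + 3 + 3) == 22


def test_joint_event_planted_extrema():
    curve = np.zeros(CYCLE_POINTS)
    curve[90] = 88.0          # sample 90/150 = 60% -> mid-swing max
    curve[52] = -9.0          # ~35% -> toe-off window minimum
    out = joint_event_features(curve, "knee_r")
    assert out["knee_r_mid_swing"] == 88.0
    assert out["knee_r_toe_off"] == -9.0


def test_joint_event_constant_curve():
    out = joint_event_features(np.full(CYCLE_POINTS, 3.5), "hip_l")
    assert all(v == 3.5 for v in out.values())


def test_unknown_joint_rejected():
    with pytest.raises(ValidationError):
        joint_event_features(np.zeros(CYCLE_POINTS), "elbow_r")


def test_symmetry_feature():
    assert symmetry_feature(10.0, 7.0) == 3.0
    assert symmetry_feature(5.0, 5.0) == 0.0


def test_spatiotemporal_arithmetic():
    out = spatiotemporal_features(0.75, 0.75, 12.0 / 3.6)
    assert len(out) == 4
    assert out["stride_time_r"] == 0.75
    assert out["stride_length_r"] == pytest.approx(2.5)
    with pytest.raises(ValidationError):
        spatiotemporal_features(0.75, 0.75, 0.0)


# ---------------------------------------------------------------------------
# full extraction and properties
# ---------------------------------------------------------------------------

def test_full_extraction_counts(random_cycle_pairs):
    pairs, speed = random_cycle_pairs
    vec = extract_feature_vector(*pairs[0], speed)
    assert len(vec) == 157
    biome = [f.name for f in CATALOGUE if f.family == "biomechanical"]
    assert len(biome) == 43
    assert all(not math.isnan(vec[n]) for n in biome)


def test_mostly_missing_curves_rejected(random_cycle_pairs):
    pairs, speed = random_cycle_pairs
    right, left = pairs[0]
    bare = {k: GaitCycle(side=c.side, start_index=c.start_index,
                         end_index=c.end_index, stride_time=c.stride_time,
                         stride_distance=c.stride_distance,
                         curves={"L6_accel_mag": c.curves["L6_accel_mag"]})
            for k, c in (("r", right), ("l", left))}
    with pytest.raises(ValidationError, match="missing"):
        extract_table([bare["r"]], [bare["l"]], speed)


@given(k=st.floats(min_value=0.1, max_value=50.0,
                   allow_nan=False, allow_infinity=False))
def test_scale_equivariance(k):
    """Scaling a curve by k scales peak/mean/STD/IQR by k, leaves
    skewness and kurtosis unchanged."""
    rng = np.random.default_rng(99)
    x = rng.standard_normal(CYCLE_POINTS) + 2.0
    base = segment_features(
        _cycle_with({"L6_accel_mag": x, "L6_angvel_pitch": x}), "L6")
    scaled = segment_features(
        _cycle_with({"L6_accel_mag": k * x, "L6_angvel_pitch": k * x}), "L6")
    for stat in ("peak", "mean", "std", "iqr"):
        assert scaled[f"L6_accel_{stat}"] == pytest.approx(
            k * base[f"L6_accel_{stat}"], rel=1e-9)
    for stat in ("skew", "kurt"):
        assert scaled[f"L6_accel_{stat}"] == pytest.approx(
            base[f"L6_accel_{stat}"], rel=1e-7, abs=1e-9)


def test_shuffle_leaves_statistical_features_unchanged():
    rng = np.random.default_rng(5)
    x = rng.standard_normal(CYCLE_POINTS)
    shuffled = rng.permutation(x)
    a = segment_features(_cycle_with({"L6_accel_mag": x,
                                      "L6_angvel_pitch": x}), "L6")
    b = segment_features(_cycle_with({"L6_accel_mag": shuffled,
                                      "L6_angvel_pitch": shuffled}), "L6")
    for stat in ("mean", "std", "iqr", "skew", "kurt", "peak"):
        assert a[f"L6_accel_{stat}"] == pytest.approx(
            b[f"L6_accel_{stat}"], abs=1e-12)
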