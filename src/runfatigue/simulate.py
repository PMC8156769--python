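"""Synthetic running-session generator.

Emulates the experimental protocol the analysis assumes: a cohort of
eight recreational runners, each completing a 4000 m constant-speed run
(10 laps of a 400 m track), a variable-length fatiguing bout (not
analysed, represented only as a standing gap) and a final constant-speed
1200 m run (3 laps).  Fatigue conditions are attached per lap: laps 2-4
of run 1 are unfatigued, laps 8-10 mildly fatigued, and the three laps of
run 3 heavily fatigued.

Strides are built from closed-form waveform templates (sums of smooth
periodic bumps and sinusoids) parameterized per stride, so that the
signals are segmentable and carry the named biomechanical landmarks:
impact peaks in the segment accelerations, a pronounced downward pelvis-
velocity peak at every right initial contact (and a minor one at the left
step), and knee-angle extension minima at both initial contacts.
Fatigue shifts the template parameters — peak tibial/sacral acceleration,
tibial pitch angular-velocity amplitude, hip flexion at initial contact,
knee swing flexion and stride-time variability — per lap, with smooth
within-lap interpolation of the condition intensity, scaled by a global
effect size and by per-subject, per-family multipliers (fatigue responses
are strongly subject-dependent in real cohorts).

With ``effect_size = 0`` all three conditions share one generating
distribution.  A single explicit RNG (NumPy PCG64) drives every draw, so
an identical seed reproduces a session bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError
from .types import LABELS, SessionRecording

# ---------------------------------------------------------------------------
# reference cohort
# ---------------------------------------------------------------------------

#: Characteristics of the eight-runner reference cohort the simulator
#: emulates: (subject, age [y], body mass [kg], height [cm],
#: speed [km/h], running experience [y], sex).
REFERENCE_COHORT: tuple[tuple[str, int, float, float, float, float, str], ...] = (
    ("S001", 25, 69.0, 182.0, 13.0, 5.0, "M"),
    ("S002", 24, 55.0, 164.0, 10.5, 3.0, "F"),
    ("S003", 23, 69.0, 167.0, 9.1, 9.0, "F"),
    ("S004", 24, 64.0, 168.0, 9.6, 7.5, "F"),
    ("S005", 25, 78.0, 174.0, 9.4, 2.0, "F"),
    ("S006", 26, 77.0, 187.0, 11.6, 1.5, "M"),
    ("S007", 23, 75.0, 169.0, 9.9, 1.5, "F"),
    ("S008", 24, 82.0, 188.0, 11.6, 6.0, "M"),
)

REFERENCE_SPEEDS_KMH: tuple[float, ...] = tuple(r[4] for r in REFERENCE_COHORT)

#: Families of fatigue response a subject can scale independently.
EFFECT_FAMILIES: tuple[str, ...] = (
    "pta", "psa", "tibia_gyro", "hip_ic", "knee_flexion", "stride_var",
)


# ---------------------------------------------------------------------------
# configuration dataclasses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunningProtocol:
    """Track-session structure (defaults match the emulated experiment)."""

    lap_length_m: float = 400.0
    laps_run1: int = 10
    laps_run3: int = 3
    sampling_rate: float = 240.0
    pre_roll_s: float = 2.0     # standing before run 1
    gap_s: float = 5.0          # standing gap replacing the fatiguing bout
    post_roll_s: float = 2.0    # standing after run 3

    @property
    def n_laps(self) -> int:
        return self.laps_run1 + self.laps_run3


@dataclass
class SubjectProfile:
    """Per-subject gait parameters (template amplitudes at baseline)."""

    subject_id: str = "S001"
    speed_kmh: float = 10.6
    stride_time_mean: float = 0.75      # s
    stride_time_cv: float = 0.02        # stride-to-stride, relative
    #: baseline waveform amplitudes
    tibial_accel_peak: float = 60.0     # m/s^2, magnitude at impact
    sacral_accel_peak: float = 30.0
    sternum_accel_peak: float = 25.0
    thigh_accel_peak: float = 38.0
    foot_accel_peak: float = 90.0
    tibia_gyro_amp: float = 450.0       # deg/s
    thigh_gyro_amp: float = 330.0
    foot_gyro_amp: float = 550.0
    pelvis_gyro_amp: float = 40.0
    sternum_gyro_amp: float = 30.0
    knee_stance_flexion: float = 32.0   # deg
    knee_swing_flexion: float = 85.0
    knee_ic_angle: float = 14.0
    hip_flexion_ic: float = 30.0
    hip_range: float = 40.0
    ankle_dorsiflexion: float = 18.0
    ankle_plantarflexion: float = 20.0
    pelvis_velocity_dip: float = 0.5    # m/s
    #: per-family fatigue-response multipliers (direction and magnitude)
    effect_multipliers: dict[str, float] = field(
        default_factory=lambda: {f: 1.0 for f in EFFECT_FAMILIES})

    def __post_init__(self) -> None:
        if self.speed_kmh <= 0:
            raise ValidationError("speed_kmh: must be > 0")
        if not 0.5 <= self.stride_time_mean <= 1.2:
            raise ValidationError("stride_time_mean: must be in [0.5, 1.2] s")
        if self.stride_time_cv < 0:
            raise ValidationError("stride_time_cv: must be >= 0")
        unknown = set(self.effect_multipliers) - set(EFFECT_FAMILIES)
        if unknown:
            raise ValidationError(f"effect_multipliers: unknown families {sorted(unknown)}")
        for f in EFFECT_FAMILIES:
            self.effect_multipliers.setdefault(f, 1.0)

    @property
    def speed_mps(self) -> float:
        return self.speed_kmh / 3.6


@dataclass
class FatigueEffectModel:
    """Fatigue-induced template shifts at full condition intensity.

    Shift directions follow the biomechanics literature on fatiguing
    runs: tibial and sacral impact peaks increase, tibial pitch
    angular-velocity variability increases, hip flexion at initial
    contact decreases, knee swing flexion shifts, stride timing becomes
    more variable.  All magnitudes are free parameters.
    """

    pta_shift: float = 8.0          # m/s^2 added to the tibial impact peak
    psa_shift: float = 3.0          # m/s^2 added to the sacral impact peak
    tibia_gyro_shift: float = 0.15  # relative increase of gyro amplitude
    hip_ic_shift: float = 4.0       # deg removed from hip flexion at IC
    knee_flexion_shift: float = 5.0  # deg added to knee swing flexion
    stride_var_shift: float = 0.5   # relative increase of stride-time CV
    effect_size: float = 1.0        # global scale; 0 = no fatigue effect
    #: intensity of each labeled condition in [0, 1]
    condition_intensity: dict[str, float] = field(default_factory=lambda: {
        "no_fatigue": 0.0, "mild_fatigue": 0.5, "heavy_fatigue": 1.0})
    # noise scales
    accel_noise: float = 0.4        # m/s^2 white noise per axis
    gyro_noise: float = 3.0         # deg/s
    angle_noise: float = 0.3        # deg
    pelvis_vel_noise: float = 0.02  # m/s
    amplitude_cv: float = 0.03      # stride-to-stride jitter of amplitudes

    def __post_init__(self) -> None:
        unknown = set(self.condition_intensity) - set(LABELS)
        if unknown:
            raise ValidationError(
                f"condition_intensity: invalid condition keys {sorted(unknown)}")
        missing = set(LABELS) - set(self.condition_intensity)
        if missing:
            raise ValidationError(
                f"condition_intensity: missing condition keys {sorted(missing)}")

    @classmethod
    def zero(cls) -> "FatigueEffectModel":
        """Null model: the three conditions are generated identically."""
        return cls(effect_size=0.0)

    @classmethod
    def strong(cls) -> "FatigueEffectModel":
        """Large, well-separated shifts (several within-subject STDs)."""
        return cls(effect_size=3.0)


@dataclass
class SessionTruth:
    """Generator ground truth for one session."""

    run_bounds: list[tuple[int, int]]       # (start, end) per run, samples
    right_ics: np.ndarray                   # right initial contacts, samples
    left_ics: np.ndarray
    stride_lap: np.ndarray                  # 0-based lap per right stride
    stride_times: np.ndarray                # s, per right stride
    stride_intensity: np.ndarray            # fatigue intensity per stride
    lap_condition: list[str]                # label per lap (13 entries)


@dataclass
class Cohort:
    """A simulated cohort: sessions with profiles and ground truth."""

    sessions: list[SessionRecording]
    truths: list[SessionTruth]
    profiles: list[SubjectProfile]


# ---------------------------------------------------------------------------
# waveform primitives
# ---------------------------------------------------------------------------

def _bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic Gaussian bump on the unit circle."""
    d = phase - center
    d -= np.round(d)
    return np.exp(-0.5 * (d / width) ** 2)


def _condition_label(lap_in_run: int, run: int) -> str:
    if run == 1 and 2 <= lap_in_run <= 4:
        return "no_fatigue"
    if run == 1 and 8 <= lap_in_run <= 10:
        return "mild_fatigue"
    if run == 3 and 1 <= lap_in_run <= 3:
        return "heavy_fatigue"
    return "excluded"


def _intensity_profile(distance: np.ndarray, run: int, lap_length: float,
                       effects: FatigueEffectModel) -> np.ndarray:
    """Fatigue intensity as a smooth function of distance within a run.

    Run 1 rises linearly from the unfatigued level (laps 1-4) across laps
    5-7 to the mild level (laps 8-10); run 3 sits at the heavy level.
    """
    i_none = effects.condition_intensity["no_fatigue"]
    i_mild = effects.condition_intensity["mild_fatigue"]
    i_heavy = effects.condition_intensity["heavy_fatigue"]
    if run == 3:
        return np.full_like(distance, i_heavy, dtype=float)
    lo, hi = 4.0 * lap_length, 7.0 * lap_length
    frac = np.clip((distance - lo) / (hi - lo), 0.0, 1.0)
    return i_none + frac * (i_mild - i_none)


# ---------------------------------------------------------------------------
# session generation
# ---------------------------------------------------------------------------

def _jitter(rng: np.random.Generator, base: float, cv: float, n: int,
            lo: float | None = None) -> np.ndarray:
    vals = base * (1.0 + cv * rng.standard_normal(n))
    if lo is not None:
        vals = np.maximum(vals, lo)
    return vals


def _synthesize_run(profile: SubjectProfile, effects: FatigueEffectModel,
                    run: int, n_laps: int, protocol: RunningProtocol,
                    rng: np.random.Generator):
    """Build one constant-speed run; returns (streams, events, n_samples)."""
    fs = protocol.sampling_rate
    speed = profile.speed_mps
    lap_len = protocol.lap_length_m
    run_dist = n_laps * lap_len
    es = effects.effect_size
    mult = profile.effect_multipliers

    # --- stride timing ---------------------------------------------------
    n_est = int(np.ceil(run_dist / (speed * profile.stride_time_mean))) + 8
    z = np.clip(rng.standard_normal(n_est), -3.0, 3.0)
    t0 = profile.stride_time_mean * (1.0 + profile.stride_time_cv * z)
    start_dist = np.concatenate([[0.0], np.cumsum(speed * t0)])[:-1]
    intensity = _intensity_profile(start_dist, run, lap_len, effects)
    cv_k = profile.stride_time_cv * (
        1.0 + effects.stride_var_shift * es * mult["stride_var"] * intensity)
    t = profile.stride_time_mean * (1.0 + cv_k * z)
    t = np.clip(t, 0.5 * profile.stride_time_mean, 1.5 * profile.stride_time_mean)
    start_dist = np.concatenate([[0.0], np.cumsum(speed * t)])[:-1]
    keep = start_dist < run_dist
    t, start_dist, intensity = t[keep], start_dist[keep], intensity[keep]
    n_strides = t.shape[0]
    if n_strides < 4:
        raise ValidationError("run too short: fewer than 4 strides generated")

    start_s = np.concatenate([[0.0], np.cumsum(t)])
    start_samples = np.round(start_s * fs).astype(int)
    n_samples = int(start_samples[-1])
    dur_samples = np.diff(start_samples)

    i = np.arange(n_samples)
    k = np.searchsorted(start_samples, i, side="right") - 1
    phase = (i - start_samples[k]) / dur_samples[k]

    # --- per-stride template parameters ---------------------------------
    cv = effects.amplitude_cv
    inten = intensity

    def shifted(base_name: str, family: str, shift: float,
                relative: bool = False) -> np.ndarray:
        base = getattr(profile, base_name)
        vals = _jitter(rng, base, cv, n_strides)
        delta = shift * es * mult[family] * inten
        return vals * (1.0 + delta) if relative else vals + delta

    # per-side parameter arrays (independent stride-to-stride jitter)
    p: dict[str, np.ndarray] = {}
    for side in ("r", "l"):
        p[f"pta_{side}"] = shifted("tibial_accel_peak", "pta", effects.pta_shift)
        p[f"tibia_gyro_{side}"] = shifted("tibia_gyro_amp", "tibia_gyro",
                                          effects.tibia_gyro_shift, relative=True)
        p[f"hip_ic_{side}"] = shifted("hip_flexion_ic", "hip_ic",
                                      -effects.hip_ic_shift)
        p[f"knee_swing_{side}"] = shifted("knee_swing_flexion", "knee_flexion",
                                          effects.knee_flexion_shift)
        p[f"foot_acc_{side}"] = _jitter(rng, profile.foot_accel_peak, cv, n_strides)
        p[f"thigh_acc_{side}"] = _jitter(rng, profile.thigh_accel_peak, cv, n_strides)
        p[f"foot_gyro_{side}"] = _jitter(rng, profile.foot_gyro_amp, cv, n_strides)
        p[f"thigh_gyro_{side}"] = _jitter(rng, profile.thigh_gyro_amp, cv, n_strides)
        p[f"knee_stance_{side}"] = _jitter(rng, profile.knee_stance_flexion, cv, n_strides)
        p[f"ankle_dorsi_{side}"] = _jitter(rng, profile.ankle_dorsiflexion, cv, n_strides)
        p[f"ankle_plantar_{side}"] = _jitter(rng, profile.ankle_plantarflexion, cv, n_strides)
    p["psa"] = shifted("sacral_accel_peak", "psa", effects.psa_shift)
    p["sternum_acc"] = _jitter(rng, profile.sternum_accel_peak, cv, n_strides)
    p["pelvis_gyro"] = _jitter(rng, profile.pelvis_gyro_amp, cv, n_strides)
    p["sternum_gyro"] = _jitter(rng, profile.sternum_gyro_amp, cv, n_strides)
    p["vel_dip"] = _jitter(rng, profile.pelvis_velocity_dip, cv, n_strides, lo=0.05)

    ps = {name: arr[k] for name, arr in p.items()}   # per-sample expansion
    g = 9.81

    def side_phase(side: str) -> np.ndarray:
        return phase if side == "r" else (phase - 0.5) % 1.0

    streams: dict[str, dict[str, np.ndarray]] = {}
    noise = rng.standard_normal  # shorthand

    def assemble(code: str, az, ax_amp, gy, gyro_scale):
        ax = ax_amp * np.sin(2.0 * np.pi * phase)
        ay = np.zeros(n_samples)
        accel = np.stack([ax, ay, az], axis=1)
        accel += effects.accel_noise * noise((n_samples, 3))
        gx = 0.20 * gyro_scale * np.sin(2.0 * np.pi * phase + 1.0)
        gz = 0.15 * gyro_scale * np.sin(2.0 * np.pi * phase + 2.0)
        angvel = np.stack([gx, gy, gz], axis=1)
        angvel += effects.gyro_noise * noise((n_samples, 3))
        streams[code] = {"accel": accel, "angvel": angvel}

    # feet (L7 right, L8 left)
    for code, side in (("L7", "r"), ("L8", "l")):
        ph = side_phase(side)
        amp = ps[f"foot_acc_{side}"]
        az = g + (amp - g) * _bump(ph, 0.01, 0.012) + 0.25 * amp * _bump(ph, 0.25, 0.06)
        gy = ps[f"foot_gyro_{side}"] * (
            0.5 * np.sin(2 * np.pi * ph - 0.4)
            + 1.0 * _bump(ph, 0.62, 0.06) - 0.8 * _bump(ph, 0.05, 0.04))
        assemble(code, az, 0.12 * amp, gy, float(np.median(amp)))

    # tibias (L5 right, L6 left)
    for code, side in (("L5", "r"), ("L6", "l")):
        ph = side_phase(side)
        pta = ps[f"pta_{side}"]
        az = g + (pta - g) * _bump(ph, 0.015, 0.015) + 4.0 * _bump(ph, 0.30, 0.10)
        gy = ps[f"tibia_gyro_{side}"] * (
            0.55 * np.sin(2 * np.pi * ph - 0.4)
            + 0.9 * _bump(ph, 0.65, 0.08) - 0.7 * _bump(ph, 0.08, 0.05))
        assemble(code, az, 0.10 * pta, gy, float(np.median(pta)))

    # thighs (L3 right, L4 left)
    for code, side in (("L3", "r"), ("L4", "l")):
        ph = side_phase(side)
        amp = ps[f"thigh_acc_{side}"]
        az = g + (amp - g) * _bump(ph, 0.02, 0.02) + 3.0 * np.sin(4 * np.pi * ph)
        gy = ps[f"thigh_gyro_{side}"] * np.sin(2 * np.pi * ph + 0.2)
        assemble(code, az, 0.10 * amp, gy, float(np.median(amp)))

    # pelvis (L2): impact of both steps, right deeper
    psa = ps["psa"]
    az = g + (psa - g) * (_bump(phase, 0.02, 0.02) + 0.85 * _bump(phase, 0.52, 0.02)) \
        + 2.0 * np.sin(4 * np.pi * phase)
    gy = ps["pelvis_gyro"] * np.sin(4 * np.pi * phase)
    assemble("L2", az, 0.08 * psa, gy, profile.pelvis_gyro_amp)

    # sternum (L1)
    st = ps["sternum_acc"]
    az = g + (st - g) * (_bump(phase, 0.03, 0.025) + 0.85 * _bump(phase, 0.53, 0.025)) \
        + 1.5 * np.sin(4 * np.pi * phase)
    gy = ps["sternum_gyro"] * np.sin(4 * np.pi * phase + 0.5)
    assemble("L1", az, 0.08 * st, gy, profile.sternum_gyro_amp)

    # joints: knee carries sharp extension minima at both ICs so initial
    # contacts are recoverable from the right knee angle alone
    joints: dict[str, np.ndarray] = {}
    notch = 6.0
    for side in ("r", "l"):
        ph = side_phase(side)
        knee = (profile.knee_ic_angle + notch
                + ps[f"knee_stance_{side}"] * _bump(ph, 0.22, 0.10)
                + ps[f"knee_swing_{side}"] * _bump(ph, 0.70, 0.10)
                - notch * (_bump(ph, 0.0, 0.025) + _bump(ph, 0.5, 0.025)))
        hip_half = profile.hip_range / 2.0
        hip = (ps[f"hip_ic_{side}"] - hip_half) + hip_half * np.cos(2 * np.pi * ph) \
            + 3.0 * np.cos(4 * np.pi * ph + 1.2)
        ankle = (ps[f"ankle_dorsi_{side}"] * _bump(ph, 0.22, 0.09)
                 - ps[f"ankle_plantar_{side}"] * _bump(ph, 0.40, 0.05)
                 + 2.0 * np.sin(2 * np.pi * ph + 0.5))
        for name, sig in (("knee", knee), ("hip", hip), ("ankle", ankle)):
            joints[f"{name}_{side}"] = sig + effects.angle_noise * noise(n_samples)

    # pelvis forward velocity: deep dip at right IC, minor dip at left step
    vel = speed - ps["vel_dip"] * (0.75 * np.cos(2 * np.pi * phase)
                                   + 0.25 * np.cos(4 * np.pi * phase))
    vel = vel + effects.pelvis_vel_noise * noise(n_samples)

    # --- events and lap bookkeeping --------------------------------------
    right_ics = start_samples[:-1]
    left_ics = start_samples[:-1] + np.round(0.5 * dur_samples).astype(int)
    stride_lap = np.minimum((start_dist // lap_len).astype(int), n_laps - 1)
    lap_starts = np.round(np.arange(n_laps) * lap_len / speed * fs).astype(int)
    lap_ends = np.concatenate([lap_starts[1:], [n_samples]])

    events = {
        "right_ics": right_ics, "left_ics": left_ics,
        "stride_lap": stride_lap, "stride_times": t,
        "stride_intensity": intensity,
        "lap_starts": lap_starts, "lap_ends": lap_ends,
    }
    return streams, joints, vel, events, n_samples


def generate_session(profile: SubjectProfile, effects: FatigueEffectModel | None = None,
                     seed: int = 0, protocol: RunningProtocol | None = None
                     ) -> tuple[SessionRecording, SessionTruth]:
    """Generate one full session (both constant-speed runs) plus ground truth."""
    effects = effects if effects is not None else FatigueEffectModel()
    protocol = protocol if protocol is not None else RunningProtocol()
    rng = np.random.default_rng(seed)
    fs = protocol.sampling_rate

    pre = int(round(protocol.pre_roll_s * fs))
    gap = int(round(protocol.gap_s * fs))
    post = int(round(protocol.post_roll_s * fs))

    parts = []
    offset = pre
    run_bounds: list[tuple[int, int]] = []
    all_lap_starts, all_lap_ends, run_of_lap, lap_condition = [], [], [], []
    right_ics, left_ics, stride_lap, stride_times, stride_int = [], [], [], [], []
    lap_offset = 0
    for run, n_laps in ((1, protocol.laps_run1), (3, protocol.laps_run3)):
        streams, joints, vel, ev, n = _synthesize_run(
            profile, effects, run, n_laps, protocol, rng)
        parts.append((offset, streams, joints, vel, n))
        run_bounds.append((offset, offset + n))
        all_lap_starts.append(ev["lap_starts"] + offset)
        all_lap_ends.append(ev["lap_ends"] + offset)
        run_of_lap.extend([run] * n_laps)
        lap_condition.extend(_condition_label(j + 1, run) for j in range(n_laps))
        right_ics.append(ev["right_ics"] + offset)
        left_ics.append(ev["left_ics"] + offset)
        stride_lap.append(ev["stride_lap"] + lap_offset)
        stride_times.append(ev["stride_times"])
        stride_int.append(ev["stride_intensity"])
        lap_offset += n_laps
        offset += n + gap
    total = offset - gap + post

    # assemble full-session streams with standing segments
    g = 9.81
    segment_streams: dict[str, dict[str, np.ndarray]] = {}
    for code in parts[0][1]:
        accel = np.zeros((total, 3))
        accel[:, 2] = g
        angvel = np.zeros((total, 3))
        for off, streams, _, _, n in parts:
            accel[off:off + n] = streams[code]["accel"]
            angvel[off:off + n] = streams[code]["angvel"]
        segment_streams[code] = {"accel": accel, "angvel": angvel}
    joint_streams: dict[str, np.ndarray] = {}
    for name in parts[0][2]:
        sig = np.zeros(total)
        for off, _, joints, _, n in parts:
            sig[off:off + n] = joints[name]
        joint_streams[name] = sig
    velocity = np.zeros(total)
    for off, _, _, vel, n in parts:
        velocity[off:off + n] = vel

    recording = SessionRecording(
        subject_id=profile.subject_id,
        sampling_rate=fs,
        segment_streams=segment_streams,
        joint_streams=joint_streams,
        pelvis_velocity=velocity,
        lap_starts=np.concatenate(all_lap_starts),
        lap_ends=np.concatenate(all_lap_ends),
        run_of_lap=run_of_lap,
        nominal_speed_kmh=profile.speed_kmh,
    )
    truth = SessionTruth(
        run_bounds=run_bounds,
        right_ics=np.concatenate(right_ics),
        left_ics=np.concatenate(left_ics),
        stride_lap=np.concatenate(stride_lap),
        stride_times=np.concatenate(stride_times),
        stride_intensity=np.concatenate(stride_int),
        lap_condition=lap_condition,
    )
    return recording, truth


def sample_profile(rng: np.random.Generator, subject_id: str,
                   effect_multiplier_sd: float = 0.35) -> SubjectProfile:
    """Draw a subject profile around the reference-cohort ranges.

    Fatigue-response multipliers are drawn per family around 1 with the
    given spread, so both magnitude and (occasionally) direction of the
    response vary between subjects.
    """
    speeds = np.array(REFERENCE_SPEEDS_KMH)
    speed = float(np.clip(rng.normal(speeds.mean(), speeds.std(ddof=1)), 8.0, 13.5))
    base = SubjectProfile(subject_id=subject_id, speed_kmh=speed)
    scale = {f: float(np.exp(rng.normal(0.0, 0.08))) for f in (
        "tibial_accel_peak", "sacral_accel_peak", "sternum_accel_peak",
        "thigh_accel_peak", "foot_accel_peak", "tibia_gyro_amp",
        "thigh_gyro_amp", "foot_gyro_amp", "knee_swing_flexion",
        "hip_flexion_ic", "ankle_dorsiflexion")}
    mults = {f: float(rng.normal(1.0, effect_multiplier_sd))
             for f in EFFECT_FAMILIES}
    return replace(
        base,
        stride_time_mean=float(np.clip(rng.normal(0.75, 0.04), 0.6, 0.9)),
        stride_time_cv=float(rng.uniform(0.015, 0.03)),
        effect_multipliers=mults,
        **{k: getattr(base, k) * v for k, v in scale.items()},
    )


def generate_cohort(n_subjects: int = 8,
                    effects: FatigueEffectModel | None = None,
                    seed: int = 0,
                    protocol: RunningProtocol | None = None,
                    effect_multiplier_sd: float = 0.35) -> Cohort:
    """Generate a cohort of synthetic sessions with ground truth."""
    if n_subjects < 2:
        raise ValidationError("n_subjects: must be >= 2")
    effects = effects if effects is not None else FatigueEffectModel()
    master = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(master.spawn(1)[0])
    session_seeds = master.spawn(n_subjects)
    sessions, truths, profiles = [], [], []
    for i in range(n_subjects):
        profile = sample_profile(profile_rng, f"S{i + 1:03d}",
                                 effect_multiplier_sd)
        rec, truth = generate_session(profile, effects,
                                      seed=session_seeds[i], protocol=protocol)
        sessions.append(rec)
        truths.append(truth)
        profiles.append(profile)
    return Cohort(sessions=sessions, truths=truths, profiles=profiles)
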