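"""Shared fixtures: small-scale synthetic sessions for fast tests.

The reduced problem sizes (40-60 Hz sampling, 60 m laps) keep unit tests
fast; the protocol structure (13 laps in two constant-speed runs, three
fatigue conditions) is always the full one.
"""

import numpy as np
import pytest
from hypothesis import settings

from runfatigue.simulate import (FatigueEffectModel, RunningProtocol,
                                 SubjectProfile, generate_session)
from runfatigue.pipeline import session_stride_features

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")

MINI_PROTOCOL = RunningProtocol(sampling_rate=40.0, lap_length_m=60.0,
                                gap_s=3.0)


@pytest.fixture(scope="session")
def mini_protocol() -> RunningProtocol:
    return MINI_PROTOCOL


@pytest.fixture(scope="session")
def mini_session(mini_protocol):
    """One small default-effect session plus its ground truth."""
    profile = SubjectProfile(subject_id="T01", speed_kmh=12.0,
                             stride_time_mean=0.75)
    return generate_session(profile, FatigueEffectModel(), seed=7,
                            protocol=mini_protocol)


@pytest.fixture(scope="session")
def mini_raw_table(mini_session):
    """Raw (unsmoothed) stride-feature table of the small session."""
    recording, _ = mini_session
    return session_stride_features(recording)


@pytest.fixture(scope="session")
def random_cycle_pairs(mini_session):
    """Five random extracted cycle pairs from the small session."""
    from runfatigue.segmentation import (derived_signals,
                                         detect_initial_contacts,
                                         detect_runs, detect_strides,
                                         pair_cycles, segment_and_normalize)
    recording, _ = mini_session
    signals = derived_signals(recording)
    bounds = detect_runs(recording.pelvis_velocity,
                         recording.sampling_rate)[0]
    peaks = detect_strides(recording.pelvis_velocity,
                           recording.sampling_rate, bounds)
    contacts = detect_initial_contacts(signals["knee_r_angle"], peaks,
                                       recording.sampling_rate)
    cycles = segment_and_normalize(recording, contacts, signals)
    pairs = pair_cycles(cycles)
    rng = np.random.default_rng(42)
    idx = rng.choice(len(pairs), size=5, replace=False)
    return [pairs[i] for i in idx], recording.nominal_speed_mps
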