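"""Sensor-placement combinatorics.

Eight instrumented locations give 255 non-empty subsets.  A subset
determines deterministically which sagittal joint angles can be computed
(a joint needs both of its adjacent segments instrumented) and therefore
which of the 157 stride features are available.  Configurations of
practical interest fall into four categories: minimally intrusive
(one IMU), quasi-minimally intrusive (selected two-IMU sets), 3+ IMUs
(selected three/four-IMU sets) and whole body (all eight).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable

from .errors import ValidationError
from .features import CATALOGUE
from .types import JOINT_SENSORS, LOCATION_CODES, SensorConfiguration

#: Two-IMU configurations of interest (adjacent or paired segments).
QUASI_MINIMAL: tuple[frozenset[str], ...] = tuple(
    frozenset(c) for c in (
        {"L2", "L3"}, {"L2", "L4"}, {"L3", "L5"}, {"L4", "L6"},
        {"L5", "L7"}, {"L6", "L8"}, {"L3", "L4"}, {"L5", "L6"}, {"L7", "L8"},
    )
)

#: Three- and four-IMU configurations of interest.
THREE_PLUS: tuple[frozenset[str], ...] = tuple(
    frozenset(c) for c in (
        {"L2", "L5", "L6"}, {"L2", "L3", "L4"}, {"L2", "L3", "L5"},
        {"L2", "L4", "L6"}, {"L3", "L5", "L7"}, {"L4", "L6", "L8"},
        {"L3", "L4", "L5", "L6"}, {"L5", "L6", "L7", "L8"},
        {"L2", "L3", "L5", "L7"}, {"L2", "L4", "L6", "L8"},
    )
)

WHOLE_BODY: frozenset[str] = frozenset(LOCATION_CODES)

#: The 28 configurations evaluated by default (8 + 9 + 10 + 1).
SELECTED_CONFIGURATIONS: tuple[frozenset[str], ...] = (
    tuple(frozenset({c}) for c in LOCATION_CODES)
    + QUASI_MINIMAL + THREE_PLUS + (WHOLE_BODY,)
)


def _check_codes(locations: Iterable[str]) -> frozenset[str]:
    locs = frozenset(locations)
    unknown = locs - set(LOCATION_CODES)
    if unknown:
        raise ValidationError(f"locations: unknown code(s) {sorted(unknown)}")
    return locs


def enumerate_subsets(locations: Iterable[str] = LOCATION_CODES
                      ) -> list[frozenset[str]]:
    """All non-empty subsets in canonical (size, then code) order."""
    locs = sorted(_check_codes(locations),
                  key=LOCATION_CODES.index)
    if not locs:
        raise ValidationError("locations: must be non-empty")
    out: list[frozenset[str]] = []
    for r in range(1, len(locs) + 1):
        out.extend(frozenset(c) for c in combinations(locs, r))
    return out


def derive_joints(locations: Iterable[str]) -> frozenset[str]:
    """Joints computable from a location subset.

    A hip needs pelvis + that side's thigh, a knee thigh + tibia, an
    ankle tibia + foot.
    """
    locs = _check_codes(locations)
    return frozenset(j for j, req in JOINT_SENSORS.items() if req <= locs)


def feature_mask(locations: Iterable[str]) -> tuple[str, ...]:
    """Catalogue features computable from a location subset, in order.

    Each feature is available iff all its required locations are present;
    masks are therefore monotone in the location set.
    """
    locs = _check_codes(locations)
    return tuple(f.name for f in CATALOGUE if f.required_locations <= locs)


def categorize(locations: Iterable[str]) -> str:
    locs = _check_codes(locations)
    if len(locs) == 1:
        return "minimally_intrusive"
    if locs in QUASI_MINIMAL:
        return "quasi_minimally_intrusive"
    if locs in THREE_PLUS:
        return "three_plus"
    if locs == WHOLE_BODY:
        return "whole_body"
    return "other"


def make_configuration(locations: Iterable[str]) -> SensorConfiguration:
    """Bundle a location subset with its derived joints, mask and category."""
    locs = _check_codes(locations)
    if not locs:
        raise ValidationError("locations: must be non-empty")
    return SensorConfiguration(
        locations=locs,
        derived_joints=derive_joints(locs),
        feature_mask=feature_mask(locs),
        category=categorize(locs),
    )
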