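"""Suitability indices: IP, IPP, reliability factor, IGCB/IGC, incidence factors.

Negative raw radii contribute zero to every mean (clamped values); the
acceptability threshold for counting a parameter as passing is applied to the
raw radius, so a negative radius can never pass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from ._util import mean
from .errors import InputValidationError
from .radii import (
    DEFAULT_REGISTRY,
    GROUPS,
    R_ACCEPTABLE,
    RadiusProfile,
)

#: Printed reliability factors; these take precedence over the polygon formula.
RELIABILITY_LOOKUP: dict[int, float] = {15: 0.971, 12: 0.952, 8: 0.900}

VERDICT_SUITABLE = "suitable"
VERDICT_NOT_SUITABLE = "not-suitable"


def polygon_reliability(n_params: int) -> float:
    """Area ratio of a regular n-gon inscribed in its circumcircle."""
    if n_params < 3:
        raise InputValidationError(f"reliability factor needs n >= 3, got {n_params}")
    return n_params * math.sin(2 * math.pi / n_params) / (2 * math.pi)


def reliability_factor(n_params) -> float:
    """Reliability factor f for ``n_params`` parameters (f = 1 at infinity).

    Published values (15 -> 0.971, 12 -> 0.952, 8 -> 0.900) take precedence;
    other counts fall back to the regular-polygon ratio.
    """
    if n_params == math.inf:
        return 1.0
    n = int(n_params)
    if n < 3:
        raise InputValidationError(f"reliability factor needs n >= 3, got {n_params}")
    return RELIABILITY_LOOKUP.get(n, polygon_reliability(n))


def parametric_index(profile: RadiusProfile) -> float:
    """IP: fraction of parameters with raw radius >= 5."""
    raw = profile.raw
    return sum(1 for r in raw.values() if r >= R_ACCEPTABLE) / len(raw)


def parameter_profile_index(profile: RadiusProfile) -> float:
    """IPP: arithmetic mean of clamped radii over the system's parameter set."""
    return mean(profile.clamped.values())


def igcb(ipp: float, f: float) -> float:
    """IGCB (odt) / IGC (classic): profile index times reliability factor."""
    if not 0 <= ipp <= 10:
        raise InputValidationError(f"IPP out of [0, 10]: {ipp}")
    if not 0 < f <= 1:
        raise InputValidationError(f"reliability factor out of (0, 1]: {f}")
    return ipp * f


def incidence_factors(profile: RadiusProfile) -> dict[str, float]:
    """Mean clamped radius per incidence-factor group present in the profile."""
    clamped = profile.clamped
    out: dict[str, float] = {}
    for group in GROUPS:
        members = [
            pid for pid in profile.parameter_ids if DEFAULT_REGISTRY[pid].group == group
        ]
        if members:
            out[group] = mean(clamped[pid] for pid in members)
    return out


@dataclass(frozen=True)
class IndexReport:
    """All suitability indices of one batch under one system."""

    batch_id: str
    system: str
    n_params: int
    n_pass: int
    ip: float
    ipp: float
    f: float
    igcb: float
    incidence: dict[str, float] = field(default_factory=dict)
    verdict: str = VERDICT_NOT_SUITABLE

    @property
    def suitable(self) -> bool:
        return self.verdict == VERDICT_SUITABLE


def full_report(profile: RadiusProfile) -> IndexReport:
    """Compute every index for ``profile``; suitable iff IGCB/IGC >= 5."""
    n = len(profile.raw)
    n_pass = sum(1 for r in profile.raw.values() if r >= R_ACCEPTABLE)
    ipp = parameter_profile_index(profile)
    f = reliability_factor(n)
    index = igcb(ipp, f)
    return IndexReport(
        batch_id=profile.batch_id,
        system=profile.system,
        n_params=n,
        n_pass=n_pass,
        ip=n_pass / n,
        ipp=ipp,
        f=f,
        igcb=index,
        incidence=incidence_factors(profile),
        verdict=VERDICT_SUITABLE if index >= R_ACCEPTABLE else VERDICT_NOT_SUITABLE,
    )
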