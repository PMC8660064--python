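"""Compendial tablet QC metrics: mechanical strength, friability, weight
variation, drug content, disintegration summary and dissolution profile."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from ._util import mean
from .errors import InputValidationError, InsufficientDataError, InvalidMeasurementError

FRIABILITY_LIMIT_PCT = 1.0
CONTENT_WINDOW_PCT = (98.0, 101.0)


@dataclass(frozen=True)
class TabletBatchQC:
    """Per-trial tablet measurements. Forces in kg-force, lengths in mm,
    weights in mg, friability masses in g, dissolution concentrations in mg/mL."""

    trial_id: str
    crushing_strengths: tuple[float, ...] = ()      # kg, n=10
    diameter: float = 0.0                           # mm (per-trial punch size)
    thicknesses: tuple[float, ...] = ()             # mm, n=10
    individual_weights: tuple[float, ...] = ()      # mg, n=20
    friability_mass_before: Optional[float] = None  # g
    friability_mass_after: Optional[float] = None   # g
    wetting_times: tuple[float, ...] = ()           # s, n=3
    disintegration_times: tuple[float, ...] = ()    # min, n=6
    peak_area_sample: Optional[float] = None
    peak_area_standard: Optional[float] = None
    dissolution_samples: tuple[tuple[float, float], ...] = ()  # (min, mg/mL)
    media_volume: float = 900.0                     # mL
    sample_volume: float = 10.0                     # mL withdrawn per sample
    label_claim: float = 100.0                      # mg per tablet

    def __post_init__(self) -> None:
        for name in ("crushing_strengths", "thicknesses", "individual_weights",
                     "wetting_times", "disintegration_times"):
            if any(v <= 0 for v in getattr(self, name)):
                raise InvalidMeasurementError(f"{name} must be strictly positive")
        if self.diameter < 0:
            raise InvalidMeasurementError("diameter must be positive")
        if self.friability_mass_before is not None and self.friability_mass_after is not None:
            if self.friability_mass_after > self.friability_mass_before:
                raise InvalidMeasurementError("friability mass increased during tumbling")
        times = [t for t, _ in self.dissolution_samples]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise InputValidationError("dissolution sampling times must strictly increase")
        if any(c < 0 for _, c in self.dissolution_samples):
            raise InvalidMeasurementError("dissolution concentrations must be non-negative")


def tensile_strength(F: float, D: float, H: float) -> float:
    """Diametral tensile strength 2F / (pi * D * H), kg/mm^2."""
    if F <= 0 or D <= 0 or H <= 0:
        raise InvalidMeasurementError(f"F, D, H must be positive, got {F}, {D}, {H}")
    return 2.0 * F / (math.pi * D * H)


def specific_crushing_strength(F: float, D: float, H: float) -> float:
    """Specific crushing strength F / (H * D), kg/mm^2."""
    if F <= 0 or D <= 0 or H <= 0:
        raise InvalidMeasurementError(f"F, D, H must be positive, got {F}, {D}, {H}")
    return F / (H * D)


def friability(mass_before: float, mass_after: float) -> float:
    """Percent mass lost in the friabilator."""
    if mass_before <= 0 or mass_after <= 0:
        raise InvalidMeasurementError("friability masses must be positive")
    if mass_after > mass_before:
        raise InvalidMeasurementError(
            f"mass after tumbling ({mass_after}) exceeds mass before ({mass_before})"
        )
    return 100.0 * (mass_before - mass_after) / mass_before


def weight_variation(weights: Sequence[float]) -> tuple[float, float]:
    """(mean weight, max absolute deviation from the mean in percent)."""
    if len(weights) < 2:
        raise InsufficientDataError("weight variation needs at least 2 tablets")
    m = mean(weights)
    return m, max(100.0 * abs(w - m) / m for w in weights)


def drug_content(peak_area_sample: float, peak_area_standard: float) -> float:
    """Percent drug content from HPLC peak-area ratio."""
    if peak_area_standard <= 0:
        raise InvalidMeasurementError("standard peak area must be positive")
    if peak_area_sample < 0:
        raise InvalidMeasurementError("sample peak area must be non-negative")
    return 100.0 * peak_area_sample / peak_area_standard


def dissolution_profile(
    samples: Sequence[tuple[float, float]],
    media_volume: float,
    sample_volume: float,
    label_claim: float,
    withdrawal_correction: bool = True,
) -> list[tuple[float, float]]:
    """Cumulative percent released at each sampling time.

    Q_t = 100 * (C_t * V_media + sum_{i<t} C_i * V_sample) / label_claim; the
    second term compensates drug removed with earlier samples (media is
    replaced with fresh buffer) and can be disabled.
    """
    if media_volume <= 0 or sample_volume < 0 or label_claim <= 0:
        raise InvalidMeasurementError("volumes and label claim must be positive")
    times = [t for t, _ in samples]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise InputValidationError("dissolution sampling times must strictly increase")
    out: list[tuple[float, float]] = []
    withdrawn = 0.0
    for t, conc in samples:
        if conc < 0:
            raise InvalidMeasurementError("concentrations must be non-negative")
        q = 100.0 * (conc * media_volume + withdrawn) / label_claim
        out.append((t, q))
        if withdrawal_correction:
            withdrawn += conc * sample_volume
    return out


def release_at(profile: Sequence[tuple[float, float]], time: float) -> float:
    """Q at ``time``, linearly interpolated between sampled points."""
    if not profile:
        raise InsufficientDataError("empty dissolution profile")
    for (t1, q1), (t2, q2) in zip(profile, profile[1:]):
        if t1 <= time <= t2:
            if t1 == time:
                return q1
            return q1 + (q2 - q1) * (time - t1) / (t2 - t1)
    if time == profile[0][0]:
        return profile[0][1]
    if time >= profile[-1][0]:
        return profile[-1][1]
    raise InputValidationError(f"time {time} precedes the first sample")


@dataclass(frozen=True)
class TabletReport:
    """Derived QC metrics with pass/fail flags for one trial."""

    trial_id: str
    mean_crushing_strength: float
    tensile_strength: float
    specific_crushing_strength: float
    mean_thickness: float
    mean_weight: Optional[float] = None
    weight_max_deviation_pct: Optional[float] = None
    friability_pct: Optional[float] = None
    friability_pass: Optional[bool] = None
    drug_content_pct: Optional[float] = None
    content_pass: Optional[bool] = None
    mean_wetting_time: Optional[float] = None
    mean_disintegration_time: Optional[float] = None
    dissolution: tuple[tuple[float, float], ...] = ()
    q15: Optional[float] = None


def batch_report(qc: TabletBatchQC, withdrawal_correction: bool = True) -> TabletReport:
    """Every derivable metric for one trial; strength metrics use mean force
    and mean thickness with the per-trial punch diameter."""
    if not qc.crushing_strengths or not qc.thicknesses or qc.diameter <= 0:
        raise InsufficientDataError(
            f"trial {qc.trial_id!r}: crushing strengths, thicknesses and diameter required"
        )
    F = mean(qc.crushing_strengths)
    H = mean(qc.thicknesses)
    report = {
        "trial_id": qc.trial_id,
        "mean_crushing_strength": F,
        "tensile_strength": tensile_strength(F, qc.diameter, H),
        "specific_crushing_strength": specific_crushing_strength(F, qc.diameter, H),
        "mean_thickness": H,
    }
    if len(qc.individual_weights) >= 2:
        mw, dev = weight_variation(qc.individual_weights)
        report["mean_weight"] = mw
        report["weight_max_deviation_pct"] = dev
    if qc.friability_mass_before is not None and qc.friability_mass_after is not None:
        fr = friability(qc.friability_mass_before, qc.friability_mass_after)
        report["friability_pct"] = fr
        report["friability_pass"] = fr < FRIABILITY_LIMIT_PCT
    if qc.peak_area_sample is not None and qc.peak_area_standard is not None:
        dc = drug_content(qc.peak_area_sample, qc.peak_area_standard)
        report["drug_content_pct"] = dc
        report["content_pass"] = CONTENT_WINDOW_PCT[0] <= dc <= CONTENT_WINDOW_PCT[1]
    if qc.wetting_times:
        report["mean_wetting_time"] = mean(qc.wetting_times)
    if qc.disintegration_times:
        report["mean_disintegration_time"] = mean(qc.disintegration_times)
    if qc.dissolution_samples:
        prof = dissolution_profile(
            qc.dissolution_samples, qc.media_volume, qc.sample_volume,
            qc.label_claim, withdrawal_correction,
        )
        report["dissolution"] = tuple(prof)
        report["q15"] = release_at(prof, 15.0)
    return TabletReport(**report)
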