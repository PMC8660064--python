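"""Granule -> tablet trend analysis and qualitative predictions.

Quantifies the claim that tablet quality attributes track granule scores:
Spearman rank correlations between granule radii/indices and tablet outcomes
are checked against an expected-sign matrix, and per-batch qualitative
predictions (compressibility, disintegration) are derived from the indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import scipy.stats

from .errors import InputValidationError
from .indices import IndexReport, full_report
from .radii import GROUP_DISGREGABILITY, R_ACCEPTABLE, SYSTEM_CLASSIC, SYSTEM_ODT, RadiusProfile

#: (granule metric, tablet metric, expected correlation sign)
DEFAULT_TRENDS: tuple[tuple[str, str, int], ...] = (
    ("Icd", "crushing_strength", +1),
    ("Icd", "wetting_time", +1),
    ("Icd", "disintegration_time", +1),
    ("Icd", "q15", -1),
    ("IGCB", "friability", -1),
)


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rho with average ranks for ties."""
    if len(x) != len(y):
        raise InputValidationError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise InputValidationError(f"rank correlation needs n >= 3, got {len(x)}")
    return float(scipy.stats.spearmanr(x, y).statistic)


@dataclass(frozen=True)
class TrendPair:
    granule_metric: str
    tablet_metric: str
    rho: float
    expected_sign: int
    agrees: bool


@dataclass(frozen=True)
class Prediction:
    batch_id: str
    suitable_for_compression: bool
    slow_disintegration_warning: Optional[bool] = None


@dataclass(frozen=True)
class LinkageReport:
    pairs: tuple[TrendPair, ...]
    predictions: tuple[Prediction, ...] = ()

    @property
    def all_agree(self) -> bool:
        return all(p.agrees for p in self.pairs)


def granule_metrics_from_profiles(
    profiles: Mapping[str, RadiusProfile]
) -> dict[str, dict[str, float]]:
    """Per-trial granule metrics (clamped radii plus the IGCB index) from
    odt radius profiles."""
    out: dict[str, dict[str, float]] = {}
    for trial, profile in profiles.items():
        metrics = dict(profile.clamped)
        metrics["IGCB"] = full_report(profile).igcb
        out[trial] = metrics
    return out


def trend_report(
    granule_metrics: Mapping[str, Mapping[str, float]],
    tablet_metrics: Mapping[str, Mapping[str, float]],
    trends: Sequence[tuple[str, str, int]] = DEFAULT_TRENDS,
    predictions: Sequence[Prediction] = (),
) -> LinkageReport:
    """Evaluate the expected-sign matrix over trials shared by both inputs."""
    trials = sorted(granule_metrics)
    if set(trials) != set(tablet_metrics):
        raise InputValidationError(
            f"unmatched trial ids: granules {sorted(granule_metrics)} "
            f"vs tablets {sorted(tablet_metrics)}"
        )
    if len(trials) < 3:
        raise InputValidationError(f"trend analysis needs >= 3 trials, got {len(trials)}")
    pairs = []
    for gm, tm, sign in trends:
        x = [granule_metrics[t][gm] for t in trials]
        y = [tablet_metrics[t][tm] for t in trials]
        rho = rank_correlation(x, y)
        pairs.append(
            TrendPair(gm, tm, rho, sign, agrees=(rho > 0) == (sign > 0) and rho != 0)
        )
    return LinkageReport(pairs=tuple(pairs), predictions=tuple(predictions))


def predict_attributes(
    report: IndexReport, companion: Optional[IndexReport] = None
) -> Prediction:
    """Qualitative prediction from the indices of one batch.

    Suitability for compression follows the classic-system IGC (>= 5, closed
    threshold); if only an odt report is supplied its own IGCB is used. A
    slow-disintegration warning fires when the Disgregability incidence is
    below 5 (only determinable from an odt report).
    """
    reports = {report.system: report}
    if companion is not None:
        if companion.batch_id != report.batch_id:
            raise InputValidationError(
                f"companion report is for {companion.batch_id!r}, not {report.batch_id!r}"
            )
        reports[companion.system] = companion
    classic = reports.get(SYSTEM_CLASSIC)
    odt = reports.get(SYSTEM_ODT)
    compress_index = (classic or report).igcb
    warning = None
    if odt is not None and GROUP_DISGREGABILITY in odt.incidence:
        warning = odt.incidence[GROUP_DISGREGABILITY] < R_ACCEPTABLE
    return Prediction(
        batch_id=report.batch_id,
        suitable_for_compression=compress_index >= R_ACCEPTABLE,
        slow_disintegration_warning=warning,
    )
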