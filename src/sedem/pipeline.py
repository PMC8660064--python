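"""End-to-end orchestration: raw measurements -> parameters -> radii ->
indices (-> tablet QC -> linkage when tablet data is present)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .config import PipelineConfig
from .errors import SedemError
from .indices import IndexReport, full_report
from .linkage import (
    LinkageReport,
    Prediction,
    granule_metrics_from_profiles,
    predict_attributes,
    trend_report,
)
from .parameters import RawMeasurements, assemble_basic_parameters
from .radii import SYSTEM_CLASSIC, SYSTEM_ODT, RadiusProfile, build_profile, registry_with_overrides
from .tablet_qc import TabletBatchQC, TabletReport, batch_report

logger = logging.getLogger(__name__)


class StageError(SedemError):
    """Wraps a stage failure with the stage and batch that caused it."""

    def __init__(self, stage: str, batch_id: str, cause: Exception):
        super().__init__(f"stage {stage!r}, batch {batch_id!r}: {cause}")
        self.stage = stage
        self.batch_id = batch_id
        self.__cause__ = cause


@dataclass
class PipelineResult:
    profiles: dict[str, dict[str, RadiusProfile]] = field(default_factory=dict)
    reports: dict[str, dict[str, IndexReport]] = field(default_factory=dict)
    tablet_reports: dict[str, TabletReport] = field(default_factory=dict)
    predictions: list[Prediction] = field(default_factory=list)
    linkage: Optional[LinkageReport] = None


def run_pipeline(
    config: PipelineConfig,
    measurements: Sequence[RawMeasurements],
    tablets: Sequence[TabletBatchQC] = (),
) -> PipelineResult:
    """Execute every stage the inputs allow, logging warnings along the way."""
    registry = (
        registry_with_overrides(config.parameter_overrides)
        if config.parameter_overrides
        else None
    )
    result = PipelineResult()
    for m in measurements:
        try:
            params = assemble_basic_parameters(m)
        except SedemError as exc:
            raise StageError("parameters", m.batch_id, exc)
        per_system_profiles: dict[str, RadiusProfile] = {}
        per_system_reports: dict[str, IndexReport] = {}
        for system in config.systems:
            try:
                profile = build_profile(params, system, batch_id=m.batch_id, registry=registry)
                per_system_profiles[system] = profile
                per_system_reports[system] = full_report(profile)
            except SedemError as exc:
                raise StageError("radii/indices", m.batch_id, exc)
        result.profiles[m.batch_id] = per_system_profiles
        result.reports[m.batch_id] = per_system_reports
        odt = per_system_reports.get(SYSTEM_ODT)
        classic = per_system_reports.get(SYSTEM_CLASSIC)
        primary = odt or classic
        companion = classic if primary is odt else None
        if primary is not None:
            result.predictions.append(predict_attributes(primary, companion))

    for qc in tablets:
        try:
            result.tablet_reports[qc.trial_id] = batch_report(
                qc, withdrawal_correction=config.dissolution_correction
            )
        except SedemError as exc:
            raise StageError("tablet_qc", qc.trial_id, exc)

    odt_profiles = {
        batch: systems[SYSTEM_ODT]
        for batch, systems in result.profiles.items()
        if SYSTEM_ODT in systems
    }
    shared = set(odt_profiles) & set(result.tablet_reports)
    if len(shared) >= 3:
        granule = granule_metrics_from_profiles(
            {b: odt_profiles[b] for b in shared}
        )
        tablet_metrics = {
            b: {
                "crushing_strength": result.tablet_reports[b].mean_crushing_strength,
                "wetting_time": result.tablet_reports[b].mean_wetting_time,
                "disintegration_time": result.tablet_reports[b].mean_disintegration_time,
                "q15": result.tablet_reports[b].q15,
                "friability": result.tablet_reports[b].friability_pct,
            }
            for b in shared
        }
        from .linkage import DEFAULT_TRENDS

        trends = tuple(
            (gm, tm, sign)
            for gm, tm, sign in DEFAULT_TRENDS
            if all(tablet_metrics[b][tm] is not None for b in shared)
        )
        try:
            result.linkage = trend_report(
                granule, tablet_metrics, trends=trends, predictions=tuple(result.predictions)
            )
        except SedemError as exc:
            logger.warning("linkage stage skipped: %s", exc)
    return result
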