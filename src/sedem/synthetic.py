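"""Synthetic two-factor granulation study generator.

Reproduces the statistical structure the analysis assumes: a 13-run design
(granulation time 30/45/60 s x binder 5/10/15 %w/w, five centre replicates)
with monotone process-variable effects on every response plus Gaussian noise.
Each response is linear in the coded levels, so a noiseless run is exactly
recoverable; sub-seeds are derived per trial from the master seed, so adding
trials never perturbs earlier ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from ._util import mean
from .errors import InputValidationError
from .indices import full_report
from .linkage import rank_correlation
from .parameters import RawMeasurements, SieveFractions, assemble_basic_parameters
from .radii import SYSTEM_ODT, build_profile
from .tablet_qc import TabletBatchQC, batch_report

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrialDesign:
    """One run of the two-factor design (coded -1/0/+1 plus actual levels)."""

    trial_id: str
    time_coded: int
    binder_coded: int
    granulation_time_s: float
    binder_concentration_pct: float


#: Coded (time, binder) levels of the 13 default runs, in run order.
_DEFAULT_CODED: tuple[tuple[int, int], ...] = (
    (0, 0), (1, -1), (0, 0), (0, 0), (1, 1), (0, 0), (0, 0),
    (-1, -1), (-1, 1), (0, -1), (1, 0), (-1, 0), (0, 1),
)


def build_design(
    time_levels: Sequence[float] = (30.0, 45.0, 60.0),
    binder_levels: Sequence[float] = (5.0, 10.0, 15.0),
) -> list[TrialDesign]:
    """The default 13-run layout (5 centre replicates) at the given levels."""
    if len(time_levels) != 3 or len(binder_levels) != 3:
        raise InputValidationError("the default design needs exactly 3 levels per factor")
    return [
        TrialDesign(
            trial_id=f"Trial-{i + 1}",
            time_coded=t,
            binder_coded=b,
            granulation_time_s=float(time_levels[t + 1]),
            binder_concentration_pct=float(binder_levels[b + 1]),
        )
        for i, (t, b) in enumerate(_DEFAULT_CODED)
    ]


def full_factorial(
    time_levels: Sequence[float], binder_levels: Sequence[float]
) -> list[TrialDesign]:
    """All level combinations, for non-default level sets."""
    if len(time_levels) < 2 or len(binder_levels) < 2:
        raise InputValidationError("each factor needs at least 2 levels")
    tc = {lvl: i - (len(time_levels) - 1) // 2 for i, lvl in enumerate(time_levels)}
    bc = {lvl: i - (len(binder_levels) - 1) // 2 for i, lvl in enumerate(binder_levels)}
    out = []
    for i, t in enumerate(time_levels):
        for j, b in enumerate(binder_levels):
            out.append(
                TrialDesign(
                    f"Trial-{i * len(binder_levels) + j + 1}", tc[t], bc[b], float(t), float(b)
                )
            )
    return out


@dataclass(frozen=True)
class ResponseEffect:
    """Linear effect of the coded factors on one response."""

    baseline: float
    binder_slope: float = 0.0
    time_slope: float = 0.0
    sd: float = 0.0
    bounds: tuple[float, float] = (-np.inf, np.inf)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InputValidationError("noise sd must be non-negative")

    def value(self, design: TrialDesign, rng: np.random.Generator) -> float:
        v = (
            self.baseline
            + self.binder_slope * design.binder_coded
            + self.time_slope * design.time_coded
        )
        if self.sd > 0:
            v += rng.normal(0.0, self.sd)
        lo, hi = self.bounds
        if not lo <= v <= hi:
            clipped = min(hi, max(lo, v))
            logger.warning("response clipped from %g to %g", v, clipped)
            v = clipped
        return v


def _default_responses() -> dict[str, ResponseEffect]:
    # Signs: binder/time raise density, cohesion and disintegration times,
    # lower flow time, fines, Q15 and friability. Magnitudes put simulated
    # odt profile indices roughly in the observed 4.4-5.5 band.
    return {
        "bulk_density": ResponseEffect(0.62, 0.040, 0.025, 0.010, (0.2, 0.95)),
        "tapped_density": ResponseEffect(0.68, 0.035, 0.020, 0.010, (0.25, 1.0)),
        "cohesion_N": ResponseEffect(120.0, 25.0, 15.0, 6.0, (5.0, 200.0)),
        "angle_deg": ResponseEffect(23.0, -1.2, -0.8, 0.5, (5.0, 50.0)),
        "flow_s": ResponseEffect(5.0, -0.7, -0.5, 0.2, (0.5, 20.0)),
        "lod_pct": ResponseEffect(2.8, 0.0, 0.0, 0.10, (0.1, 10.0)),
        "hygro_pct": ResponseEffect(3.8, 0.0, 0.0, 0.10, (0.1, 20.0)),
        "fines_pct": ResponseEffect(8.0, -1.5, -1.0, 0.5, (0.5, 50.0)),
        "size_center": ResponseEffect(2.5, -0.30, -0.20, 0.10, (0.0, 5.0)),
        "de_min": ResponseEffect(3.5, 0.8, 0.5, 0.15, (0.1, 30.0)),
        "dcd_min": ResponseEffect(2.0, 0.5, 0.3, 0.10, (0.05, 30.0)),
        "dsd_min": ResponseEffect(3.0, 0.8, 0.5, 0.15, (0.05, 30.0)),
        "crush_kg": ResponseEffect(8.5, 2.0, 1.2, 0.40, (1.0, 20.0)),
        "thickness_mm": ResponseEffect(3.5, -0.05, -0.03, 0.03, (2.0, 5.0)),
        "weight_mg": ResponseEffect(250.0, 0.0, 0.0, 2.0, (200.0, 300.0)),
        "wetting_s": ResponseEffect(185.0, 30.0, 15.0, 8.0, (10.0, 600.0)),
        "disint_min": ResponseEffect(9.0, 1.5, 1.0, 0.40, (0.5, 60.0)),
        "q15_pct": ResponseEffect(60.0, -10.0, -6.0, 2.0, (1.0, 88.0)),
        "content_pct": ResponseEffect(99.5, 0.0, 0.0, 0.40, (90.0, 110.0)),
        "friability_pct": ResponseEffect(0.50, -0.12, -0.08, 0.04, (0.01, 5.0)),
    }


@dataclass(frozen=True)
class EffectConfig:
    """Baselines, slopes and noise SDs for every simulated response."""

    responses: dict[str, ResponseEffect] = field(default_factory=_default_responses)
    replicate_cv: float = 0.02  # within-trial replicate scatter, fraction of the value
    seed: int = 0

    def scaled_noise(self, factor: float) -> "EffectConfig":
        """Copy with every noise sd (and replicate scatter) multiplied by ``factor``."""
        return EffectConfig(
            responses={
                k: replace(r, sd=r.sd * factor) for k, r in self.responses.items()
            },
            replicate_cv=self.replicate_cv * factor,
            seed=self.seed,
        )

    def with_inverted_slopes(self) -> "EffectConfig":
        return EffectConfig(
            responses={
                k: replace(r, binder_slope=-r.binder_slope, time_slope=-r.time_slope)
                for k, r in self.responses.items()
            },
            replicate_cv=self.replicate_cv,
            seed=self.seed,
        )


SIEVE_APERTURES = (850.0, 600.0, 425.0, 300.0, 250.0, 50.0)

DISSOLUTION_TIMES = (0.0, 5.0, 15.0, 30.0, 60.0)


def _replicates(value: float, n: int, cv: float, rng: np.random.Generator) -> tuple[float, ...]:
    if cv <= 0:
        return (value,) * n
    draws = value * (1.0 + rng.normal(0.0, cv, size=n))
    return tuple(float(max(d, value * 0.1)) for d in draws)


def _sieve_fractions(center: float, fines_pct: float, rng: np.random.Generator) -> SieveFractions:
    # discretised bell over the 6 retained fractions; lower center = coarser
    idx = np.arange(len(SIEVE_APERTURES), dtype=float)
    weights = np.exp(-((idx - center) ** 2) / (2 * 1.2**2))
    weights = weights / weights.sum() * (100.0 - fines_pct)
    return SieveFractions(
        fractions=tuple(zip(SIEVE_APERTURES, (float(w) for w in weights))),
        pan_percent=fines_pct,
    )


def _dissolution_samples(q15_pct: float, label_claim: float, media_volume: float):
    # first-order release C(t) = claim * Fmax (1 - exp(-kt)) / V, k set so the
    # naive (uncorrected) Q at 15 min equals the target
    fmax = 0.92
    frac15 = min(q15_pct / 100.0, fmax * 0.999)
    k = -np.log(1.0 - frac15 / fmax) / 15.0
    return tuple(
        (t, float(label_claim * fmax * (1.0 - np.exp(-k * t)) / media_volume))
        for t in DISSOLUTION_TIMES
    )


def trial_rng(master_seed: int, trial_index: int) -> np.random.Generator:
    """Deterministic per-trial generator: SeedSequence([master_seed, index])."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), int(trial_index)]))


def simulate_trial(
    design: TrialDesign,
    cfg: EffectConfig,
    seed: int,
    trial_index: int = 0,
) -> tuple[RawMeasurements, TabletBatchQC]:
    """Generate one trial's raw granule measurements and tablet QC record."""
    rng = trial_rng(seed, trial_index)
    r = {name: eff.value(design, rng) for name, eff in cfg.responses.items()}
    if r["tapped_density"] < r["bulk_density"]:
        logger.warning(
            "%s: tapped density %.4f below bulk %.4f after noise; truncating",
            design.trial_id, r["tapped_density"], r["bulk_density"],
        )
        r["tapped_density"] = r["bulk_density"]
    cv = cfg.replicate_cv
    mass = 100.0
    cone_radius = 50.0
    raw = RawMeasurements(
        batch_id=design.trial_id,
        granule_mass=mass,
        bulk_volume=mass / r["bulk_density"],
        tapped_volume=mass / r["tapped_density"],
        cone_height=cone_radius * float(np.tan(np.radians(r["angle_deg"]))),
        cone_radius=cone_radius,
        flow_time=r["flow_s"],
        loss_on_drying_pct=r["lod_pct"],
        hygroscopicity_pct=r["hygro_pct"],
        compact_strengths=_replicates(r["cohesion_N"], 10, cv, rng),
        sieve_fractions=_sieve_fractions(r["size_center"], r["fines_pct"], rng),
        percent_fines=r["fines_pct"],
        effervescence_times=_replicates(r["de_min"], 6, cv, rng),
        disint_disk_times=_replicates(r["dcd_min"], 6, cv, rng),
        disint_nodisk_times=_replicates(r["dsd_min"], 6, cv, rng),
    )
    label_claim, media_volume = 100.0, 900.0
    qc = TabletBatchQC(
        trial_id=design.trial_id,
        crushing_strengths=_replicates(r["crush_kg"], 10, cv, rng),
        diameter=10.5,
        thicknesses=_replicates(r["thickness_mm"], 10, cv, rng),
        individual_weights=_replicates(r["weight_mg"], 20, cv, rng),
        friability_mass_before=6.5,
        friability_mass_after=6.5 * (1.0 - r["friability_pct"] / 100.0),
        wetting_times=_replicates(r["wetting_s"], 3, cv, rng),
        disintegration_times=_replicates(r["disint_min"], 6, cv, rng),
        peak_area_sample=10.0 * r["content_pct"],
        peak_area_standard=1000.0,
        dissolution_samples=_dissolution_samples(r["q15_pct"], label_claim, media_volume),
        media_volume=media_volume,
        sample_volume=10.0,
        label_claim=label_claim,
    )
    return raw, qc


def simulate_study(
    cfg: Optional[EffectConfig] = None,
    seed: Optional[int] = None,
    design: Optional[Sequence[TrialDesign]] = None,
) -> list[tuple[TrialDesign, RawMeasurements, TabletBatchQC]]:
    """Simulate every trial of the design with per-trial sub-seeds."""
    cfg = cfg or EffectConfig()
    seed = cfg.seed if seed is None else seed
    design = list(design) if design is not None else build_design()
    return [
        (d, *simulate_trial(d, cfg, seed, trial_index=i)) for i, d in enumerate(design)
    ]


#: (factor, response, expected correlation sign) checked by recovery_check.
DEFAULT_EXPECTED_SIGNS: tuple[tuple[str, str, int], ...] = (
    ("binder", "cohesion_N", +1),
    ("time", "cohesion_N", +1),
    ("binder", "disintegration_min", +1),
    ("time", "disintegration_min", +1),
    ("binder", "q15_pct", -1),
    ("time", "q15_pct", -1),
)


@dataclass(frozen=True)
class RecoveryCheck:
    factor: str
    response: str
    expected_sign: int
    rho: float
    passed: bool


@dataclass(frozen=True)
class RecoveryResult:
    checks: tuple[RecoveryCheck, ...]
    profiles_suitable: tuple[str, ...]

    @property
    def all_passed(self) -> bool:
        return all(c.passed for c in self.checks)


def recovery_check(
    study: Sequence[tuple[TrialDesign, RawMeasurements, TabletBatchQC]],
    expected_signs: Sequence[tuple[str, str, int]] = DEFAULT_EXPECTED_SIGNS,
) -> RecoveryResult:
    """Run the full pipeline on a simulated study and verify effect signs.

    Responses observed through the pipeline: the cohesion-index V (mean
    compact strength), the tablet disintegration time, and Q15 from the
    dissolution profile.
    """
    if len(study) < 9:
        raise InputValidationError(f"recovery check needs >= 9 trials, got {len(study)}")
    levels = {"binder": [], "time": []}
    observed: dict[str, list[float]] = {
        "cohesion_N": [], "disintegration_min": [], "q15_pct": []
    }
    suitable: list[str] = []
    for design, raw, qc in study:
        params = assemble_basic_parameters(raw)
        profile = build_profile(params, SYSTEM_ODT, batch_id=design.trial_id)
        report = full_report(profile)
        if report.suitable:
            suitable.append(design.trial_id)
        tablet = batch_report(qc)
        levels["binder"].append(design.binder_coded)
        levels["time"].append(design.time_coded)
        observed["cohesion_N"].append(params.Icd)
        observed["disintegration_min"].append(tablet.mean_disintegration_time)
        observed["q15_pct"].append(tablet.q15)
    checks = []
    for factor, response, sign in expected_signs:
        rho = rank_correlation(levels[factor], observed[response])
        checks.append(
            RecoveryCheck(factor, response, sign, rho, passed=(rho > 0) == (sign > 0) and rho != 0)
        )
    return RecoveryResult(checks=tuple(checks), profiles_suitable=tuple(suitable))
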