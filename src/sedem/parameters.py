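"""The 15 basic granule/powder parameters (experimental values V).

Each single-purpose operation computes one parameter from its raw inputs;
:func:`assemble_basic_parameters` composes them into a :class:`BasicParameters`
record, the entry point of the scoring pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Optional, Sequence

from ._util import mean
from .errors import (
    InputValidationError,
    InsufficientDataError,
    InvalidMeasurementError,
    MissingFieldError,
)

logger = logging.getLogger(__name__)

#: Tolerance on the sieve-fraction mass balance (percent).
SIEVE_TOTAL_TOL = 0.5


@dataclass(frozen=True)
class SieveFractions:
    """Sieve analysis of one batch.

    ``fractions`` lists ``(aperture_um, percent_retained)`` in strictly
    decreasing aperture order; ``pan_percent`` is the mass passing the finest
    sieve. Percentages must balance to 100 within ``SIEVE_TOTAL_TOL``.
    """

    fractions: tuple[tuple[float, float], ...]
    pan_percent: float = 0.0

    def __post_init__(self) -> None:
        if not self.fractions:
            raise InsufficientDataError("sieve analysis needs at least one fraction")
        apertures = [a for a, _ in self.fractions]
        if any(b >= a for a, b in zip(apertures, apertures[1:])):
            raise InputValidationError(f"sieve apertures must strictly decrease, got {apertures}")
        if any(a <= 0 for a in apertures):
            raise InputValidationError("sieve apertures must be positive")
        if any(p < 0 for _, p in self.fractions) or self.pan_percent < 0:
            raise InputValidationError("sieve percentages must be non-negative")
        if abs(self.total - 100.0) > SIEVE_TOTAL_TOL:
            raise InputValidationError(
                f"sieve fractions must total 100 +/- {SIEVE_TOTAL_TOL}, got {self.total:.3f}"
            )

    @property
    def total(self) -> float:
        return sum(p for _, p in self.fractions) + self.pan_percent

    @classmethod
    def from_raw_masses(
        cls, apertures: Sequence[float], masses: Sequence[float], pan_mass: float = 0.0
    ) -> "SieveFractions":
        """Build from retained masses (any unit), normalising to 100 percent."""
        if len(apertures) != len(masses):
            raise InputValidationError("apertures and masses must have equal length")
        total = sum(masses) + pan_mass
        if total <= 0:
            raise InsufficientDataError("total sieved mass must be positive")
        return cls(
            fractions=tuple(
                (float(a), 100.0 * m / total) for a, m in zip(apertures, masses)
            ),
            pan_percent=100.0 * pan_mass / total,
        )

    def bins(self) -> list[tuple[str, float, float]]:
        """``(label, mean_diameter_um, percent)`` for every fraction plus the pan.

        Mean diameter is the midpoint of the bounding apertures; the coarsest
        fraction (no upper sieve) is assigned its own aperture, the pan half of
        the finest aperture.
        """
        out: list[tuple[str, float, float]] = []
        prev: Optional[float] = None
        for aperture, pct in self.fractions:
            diam = aperture if prev is None else (prev + aperture) / 2.0
            out.append((f"retained_{aperture:g}", diam, pct))
            prev = aperture
        finest = self.fractions[-1][0]
        out.append((f"pan_{finest:g}", finest / 2.0, self.pan_percent))
        return out


@dataclass(frozen=True)
class RawMeasurements:
    """One batch's raw lab observations.

    Any field may be ``None`` when the corresponding test was not run;
    :func:`assemble_basic_parameters` reports which parameters that blocks.
    Replicate lists (compact strengths, disintegration times) are aggregated
    by arithmetic mean downstream.
    """

    batch_id: str
    granule_mass: Optional[float] = None            # g
    bulk_volume: Optional[float] = None             # mL
    tapped_volume: Optional[float] = None           # mL
    cone_height: Optional[float] = None             # mm
    cone_radius: Optional[float] = None             # mm
    flow_time: Optional[float] = None               # s per 100 g
    loss_on_drying_pct: Optional[float] = None      # % weight loss
    hygroscopicity_pct: Optional[float] = None      # % weight gain / 24 h
    compact_strengths: Optional[tuple[float, ...]] = None  # N, n=10
    sieve_fractions: Optional[SieveFractions] = None
    percent_fines: Optional[float] = None           # % below 50 um
    effervescence_times: Optional[tuple[float, ...]] = None  # min, n=6
    disint_disk_times: Optional[tuple[float, ...]] = None    # min, n=6
    disint_nodisk_times: Optional[tuple[float, ...]] = None  # min, n=6

    def __post_init__(self) -> None:
        positive = (
            "granule_mass", "bulk_volume", "tapped_volume", "cone_radius", "flow_time",
        )
        for name in positive:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise InvalidMeasurementError(f"{name} must be strictly positive, got {v}")
        nonneg = ("cone_height", "loss_on_drying_pct", "hygroscopicity_pct", "percent_fines")
        for name in nonneg:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidMeasurementError(f"{name} must be non-negative, got {v}")
        if self.bulk_volume is not None and self.tapped_volume is not None:
            if self.tapped_volume > self.bulk_volume:
                raise InvalidMeasurementError(
                    f"tapped_volume ({self.tapped_volume}) cannot exceed "
                    f"bulk_volume ({self.bulk_volume})"
                )
        for name in (
            "compact_strengths", "effervescence_times",
            "disint_disk_times", "disint_nodisk_times",
        ):
            v = getattr(self, name)
            if v is not None:
                if len(v) < 1:
                    raise InsufficientDataError(f"{name} must contain at least one value")
                if any(x < 0 for x in v):
                    raise InvalidMeasurementError(f"{name} values must be non-negative")


@dataclass(frozen=True)
class BasicParameters:
    """The 15 experimental/calculated V values, one field per parameter id."""

    Da: float        # bulk density, g/mL
    Dc: float        # tapped density, g/mL
    Ie: float        # inter-particle porosity, -
    Ic: float        # Carr's index, %
    Icd: float       # cohesion index, N
    IH: float        # Hausner ratio, -
    alpha: float     # angle of repose, degrees
    t_flow: float    # powder flow, s / 100 g
    HR: float        # loss on drying, %
    H: float         # hygroscopicity, %
    Pf: float        # particles < 50 um, %
    Itheta: float    # homogeneity index, -
    DE: float        # effervescence time, min
    DCD: float       # disintegration time with disk, min
    DSD: float       # disintegration time without disk, min

    _FIELD_TO_ID = {"t_flow": "t"}

    def __post_init__(self) -> None:
        if self.Da > self.Dc:
            raise InvalidMeasurementError(f"Da ({self.Da}) cannot exceed Dc ({self.Dc})")
        if self.Ie < 0 or self.Itheta < 0:
            raise InvalidMeasurementError("Ie and Itheta must be non-negative")
        if not 0 <= self.Ic < 100:
            raise InvalidMeasurementError(f"Carr's index out of [0, 100): {self.Ic}")
        if self.IH < 1:
            raise InvalidMeasurementError(f"Hausner ratio below 1: {self.IH}")
        if not 0 <= self.alpha < 90:
            raise InvalidMeasurementError(f"angle of repose out of [0, 90): {self.alpha}")
        for name in ("Icd", "t_flow", "HR", "H", "Pf", "DE", "DCD", "DSD"):
            if getattr(self, name) < 0:
                raise InvalidMeasurementError(f"{name} must be non-negative")

    def as_dict(self) -> dict[str, float]:
        """Values keyed by canonical parameter id, in registry order."""
        out = {}
        for f in fields(self):
            pid = self._FIELD_TO_ID.get(f.name, f.name)
            out[pid] = getattr(self, f.name)
        return out


# ---------------------------------------------------------------------------
# single-purpose operations


def density_from_mass_volume(mass: float, volume: float) -> float:
    """Bulk or tapped density: mass (g) over volume (mL)."""
    if mass <= 0 or volume <= 0:
        raise InvalidMeasurementError(f"mass and volume must be positive, got {mass}, {volume}")
    return mass / volume


def interparticle_porosity(Da: float, Dc: float) -> float:
    """Ie = (Dc - Da) / (Dc * Da); zero when the densities coincide."""
    if Da <= 0 or Dc <= 0:
        raise InvalidMeasurementError("densities must be positive")
    if Da > Dc:
        raise InvalidMeasurementError(f"bulk density {Da} exceeds tapped density {Dc}")
    return (Dc - Da) / (Dc * Da)


def carr_index(Da: float, Dc: float) -> float:
    """Carr's compressibility index, 100 * (Dc - Da) / Dc, in percent."""
    if Da <= 0 or Dc <= 0:
        raise InvalidMeasurementError("densities must be positive")
    if Da > Dc:
        raise InvalidMeasurementError(f"bulk density {Da} exceeds tapped density {Dc}")
    return 100.0 * (Dc - Da) / Dc


def hausner_ratio(Da: float, Dc: float) -> float:
    """Hausner ratio Dc / Da."""
    if Da <= 0:
        raise InvalidMeasurementError("bulk density must be positive")
    if Dc < Da:
        raise InvalidMeasurementError(f"bulk density {Da} exceeds tapped density {Dc}")
    return Dc / Da


def angle_of_repose(height: float, radius: float) -> float:
    """arctan(h / r) in degrees; height and radius in the same length unit."""
    if radius <= 0:
        raise InvalidMeasurementError(f"cone radius must be positive, got {radius}")
    if height < 0:
        raise InvalidMeasurementError(f"cone height must be non-negative, got {height}")
    return math.degrees(math.atan(height / radius))


def cohesion_index(compact_strengths: Sequence[float]) -> float:
    """Mean crushing strength (N) of compacts pressed just below capping."""
    if not compact_strengths:
        raise InsufficientDataError("cohesion index needs at least one crushing strength")
    if any(s < 0 for s in compact_strengths):
        raise InvalidMeasurementError("crushing strengths must be non-negative")
    return mean(compact_strengths)


KGF_TO_NEWTON = 9.80665


def kgf_to_newton(value_kgf: float) -> float:
    """Convert a crushing force reported in kg-force to newtons."""
    return value_kgf * KGF_TO_NEWTON


def homogeneity_index(fractions: SieveFractions) -> float:
    """Granulometric homogeneity Itheta = Fm / (100 + sum |dm - dn| * Fn).

    Fm is the percent mass of the majority fraction, Fn the percent mass of
    every other fraction (pan included) and dm, dn their mean diameters in
    micrometres. Reduces to Fm/100 when all mass sits in one fraction.
    """
    bins = fractions.bins()
    # tie on percent -> the coarser fraction wins (deterministic, logged)
    best = max(bins, key=lambda b: (b[2], b[1]))
    ties = [b for b in bins if b[2] == best[2]]
    if len(ties) > 1:
        logger.warning(
            "majority-fraction tie at %.3f%% between %s; choosing %s",
            best[2], [b[0] for b in ties], best[0],
        )
    fm, dm = best[2], best[1]
    if fm <= 0:
        raise InsufficientDataError("all sieve fractions are empty")
    denom = 100.0 + sum(abs(dm - d) * pct for label, d, pct in bins if label != best[0])
    return fm / denom


def assemble_basic_parameters(m: RawMeasurements) -> BasicParameters:
    """Compute all 15 parameters from one batch's raw measurements.

    Raises :class:`MissingFieldError` listing every parameter blocked by an
    absent input field.
    """
    requirements: dict[str, tuple[str, ...]] = {
        "Da": ("granule_mass", "bulk_volume"),
        "Dc": ("granule_mass", "tapped_volume"),
        "Ie": ("granule_mass", "bulk_volume", "tapped_volume"),
        "Ic": ("granule_mass", "bulk_volume", "tapped_volume"),
        "Icd": ("compact_strengths",),
        "IH": ("granule_mass", "bulk_volume", "tapped_volume"),
        "alpha": ("cone_height", "cone_radius"),
        "t": ("flow_time",),
        "HR": ("loss_on_drying_pct",),
        "H": ("hygroscopicity_pct",),
        "Pf": ("percent_fines",),
        "Itheta": ("sieve_fractions",),
        "DE": ("effervescence_times",),
        "DCD": ("disint_disk_times",),
        "DSD": ("disint_nodisk_times",),
    }
    blocked = sorted(
        pid for pid, needs in requirements.items()
        if any(getattr(m, field) is None for field in needs)
    )
    if blocked:
        missing_fields = sorted(
            {f for pid in blocked for f in requirements[pid] if getattr(m, f) is None}
        )
        raise MissingFieldError(
            f"batch {m.batch_id!r}: missing field(s) {missing_fields} "
            f"block parameter(s) {blocked}",
            parameters=blocked,
        )

    Da = density_from_mass_volume(m.granule_mass, m.bulk_volume)
    Dc = density_from_mass_volume(m.granule_mass, m.tapped_volume)
    return BasicParameters(
        Da=Da,
        Dc=Dc,
        Ie=interparticle_porosity(Da, Dc),
        Ic=carr_index(Da, Dc),
        Icd=cohesion_index(m.compact_strengths),
        IH=hausner_ratio(Da, Dc),
        alpha=angle_of_repose(m.cone_height, m.cone_radius),
        t_flow=m.flow_time,
        HR=m.loss_on_drying_pct,
        H=m.hygroscopicity_pct,
        Pf=m.percent_fines,
        Itheta=homogeneity_index(m.sieve_fractions),
        DE=mean(m.effervescence_times),
        DCD=mean(m.disint_disk_times),
        DSD=mean(m.disint_nodisk_times),
    )
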