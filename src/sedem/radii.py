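"""Transform experimental values V into 0-10 radius values r.

Every applied factor is affine in V (``r = intercept + slope * V``) with the
constants used exactly as printed in the methodology (notably 3.33 for the
disintegration-time factors, so their ceiling is 9.99, not 10). Raw radii are
kept alongside clamped radii: indices and diagrams consume clamped values,
reports show both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional

from .errors import MissingFieldError, RegistryError
from .parameters import BasicParameters

logger = logging.getLogger(__name__)

GROUP_DIMENSION = "Dimension"
GROUP_COMPRESSIBILITY = "Compressibility"
GROUP_FLOWABILITY = "Flowability/Powder Flow"
GROUP_LUBRICITY_STABILITY = "Lubricity/Stability"
GROUP_LUBRICITY_DOSAGE = "Lubricity/Dosage"
GROUP_DISGREGABILITY = "Disgregability"

GROUPS = (
    GROUP_DIMENSION,
    GROUP_COMPRESSIBILITY,
    GROUP_FLOWABILITY,
    GROUP_LUBRICITY_STABILITY,
    GROUP_LUBRICITY_DOSAGE,
    GROUP_DISGREGABILITY,
)

SYSTEM_ODT = "odt"
SYSTEM_CLASSIC = "classic"


@dataclass(frozen=True)
class ParameterSpec:
    """Registry entry for one parameter: group, admissible V range, factor."""

    id: str
    name: str
    group: str
    unit: str
    v_limits: tuple[float, float]
    intercept: float
    slope: float
    in_classic_subset: bool = True

    def radius(self, v: float) -> float:
        return self.intercept + self.slope * v

    def inverse(self, r: float) -> float:
        return (r - self.intercept) / self.slope

    @property
    def favorable_v(self) -> float:
        """The admissible V value with the highest radius."""
        low, high = self.v_limits
        return high if self.slope > 0 else low


def _spec(pid, name, group, unit, limits, intercept, slope, classic=True):
    return ParameterSpec(pid, name, group, unit, limits, intercept, slope, classic)


#: Canonical registry in diagram order. Factors, limits and groups as printed.
DEFAULT_REGISTRY: dict[str, ParameterSpec] = {
    s.id: s
    for s in (
        _spec("Da", "Bulk density", GROUP_DIMENSION, "g/mL", (0.0, 1.0), 0.0, 10.0),
        _spec("Dc", "Tapped density", GROUP_DIMENSION, "g/mL", (0.0, 1.0), 0.0, 10.0),
        _spec("Ie", "Inter-particle porosity", GROUP_COMPRESSIBILITY, "-", (0.0, 1.2), 0.0, 10.0 / 1.2),
        _spec("Ic", "Carr's index", GROUP_COMPRESSIBILITY, "%", (0.0, 50.0), 0.0, 1.0 / 5.0),
        _spec("Icd", "Cohesion index", GROUP_COMPRESSIBILITY, "N", (0.0, 200.0), 0.0, 1.0 / 20.0),
        _spec("IH", "Hausner ratio", GROUP_FLOWABILITY, "-", (1.0, 3.0), 15.0, -5.0),
        _spec("alpha", "Angle of repose", GROUP_FLOWABILITY, "deg", (0.0, 50.0), 10.0, -1.0 / 5.0),
        _spec("t", "Powder flow", GROUP_FLOWABILITY, "s", (0.0, 20.0), 10.0, -1.0 / 2.0),
        _spec("HR", "Loss on drying", GROUP_LUBRICITY_STABILITY, "%", (0.0, 10.0), 10.0, -1.0),
        _spec("H", "Hygroscopicity", GROUP_LUBRICITY_STABILITY, "%", (0.0, 20.0), 10.0, -1.0 / 2.0),
        _spec("Pf", "Particles < 50 um", GROUP_LUBRICITY_DOSAGE, "%", (0.0, 50.0), 10.0, -1.0 / 5.0),
        _spec("Itheta", "Homogeneity index", GROUP_LUBRICITY_DOSAGE, "-", (0.0, 0.02), 0.0, 500.0),
        _spec("DE", "Effervescence time", GROUP_DISGREGABILITY, "min", (0.0, 5.0), 10.0, -2.0, classic=False),
        _spec("DCD", "Disintegration time with disk", GROUP_DISGREGABILITY, "min", (0.0, 3.0), 9.99, -3.33, classic=False),
        _spec("DSD", "Disintegration time without disk", GROUP_DISGREGABILITY, "min", (0.0, 3.0), 9.99, -3.33, classic=False),
    )
}

PARAMETER_ORDER: tuple[str, ...] = tuple(DEFAULT_REGISTRY)
CLASSIC_ORDER: tuple[str, ...] = tuple(
    pid for pid in PARAMETER_ORDER if DEFAULT_REGISTRY[pid].in_classic_subset
)

R_MIN, R_MAX = 0.0, 10.0
R_ACCEPTABLE = 5.0


def system_parameter_ids(system: str, registry: Optional[Mapping[str, ParameterSpec]] = None) -> tuple[str, ...]:
    registry = registry or DEFAULT_REGISTRY
    if system == SYSTEM_ODT:
        return tuple(registry)
    if system == SYSTEM_CLASSIC:
        return tuple(pid for pid, s in registry.items() if s.in_classic_subset)
    raise RegistryError(f"unknown system {system!r}; expected 'odt' or 'classic'")


def registry_with_overrides(
    overrides: Mapping[str, Mapping[str, object]],
    registry: Optional[Mapping[str, ParameterSpec]] = None,
) -> dict[str, ParameterSpec]:
    """New registry with per-parameter ``v_limits`` / ``intercept`` / ``slope`` replaced."""
    base = dict(registry or DEFAULT_REGISTRY)
    allowed = {"v_limits", "intercept", "slope"}
    for pid, fields in overrides.items():
        if pid not in base:
            raise RegistryError(f"unknown parameter id {pid!r} in overrides")
        bad = set(fields) - allowed
        if bad:
            raise RegistryError(f"cannot override {sorted(bad)} for {pid!r}")
        if "v_limits" in fields:
            fields = dict(fields)
            fields["v_limits"] = tuple(fields["v_limits"])  # type: ignore[arg-type]
        base[pid] = replace(base[pid], **fields)  # type: ignore[arg-type]
    return base


def radius_value(
    parameter_id: str,
    v: float,
    registry: Optional[Mapping[str, ParameterSpec]] = None,
) -> float:
    """Apply the printed factor for ``parameter_id`` to V. No clamping."""
    registry = registry or DEFAULT_REGISTRY
    try:
        spec = registry[parameter_id]
    except KeyError:
        raise RegistryError(f"unknown parameter id {parameter_id!r}") from None
    low, high = spec.v_limits
    if not low <= v <= high:
        logger.warning(
            "parameter %s: V=%g outside admissible limits [%g, %g]; transforming anyway",
            parameter_id, v, low, high,
        )
    return spec.radius(v)


def clamp_radius(raw_r: float) -> float:
    """Clamp a raw radius onto the diagram scale [0, 10]."""
    return min(R_MAX, max(R_MIN, raw_r))


@dataclass(frozen=True)
class RadiusProfile:
    """Raw and clamped radii of one batch under one system (odt=15, classic=12)."""

    batch_id: str
    system: str
    raw: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = system_parameter_ids(self.system)
        got = tuple(self.raw)
        if set(got) != set(expected):
            missing = sorted(set(expected) - set(got))
            extra = sorted(set(got) - set(expected))
            raise MissingFieldError(
                f"profile {self.batch_id!r} ({self.system}): "
                f"missing {missing}, unexpected {extra}",
                parameters=missing,
            )
        # normalise ordering to the canonical diagram order
        object.__setattr__(self, "raw", {pid: float(self.raw[pid]) for pid in expected})

    @property
    def parameter_ids(self) -> tuple[str, ...]:
        return tuple(self.raw)

    @property
    def clamped(self) -> dict[str, float]:
        return {pid: clamp_radius(r) for pid, r in self.raw.items()}

    @classmethod
    def from_radii(cls, batch_id: str, radii: Mapping[str, float], system: str = SYSTEM_ODT) -> "RadiusProfile":
        """Build a profile from pre-computed radii, selecting the system subset."""
        wanted = system_parameter_ids(system)
        missing = [pid for pid in wanted if pid not in radii]
        if missing:
            raise MissingFieldError(
                f"profile {batch_id!r} ({system}): missing radii for {missing}",
                parameters=missing,
            )
        return cls(batch_id, system, {pid: radii[pid] for pid in wanted})

    def subset(self, system: str) -> "RadiusProfile":
        """Project an odt profile onto the classic 12-parameter subset."""
        return RadiusProfile.from_radii(self.batch_id, self.raw, system)


def build_profile(
    params: BasicParameters,
    system: str = SYSTEM_ODT,
    batch_id: str = "",
    registry: Optional[Mapping[str, ParameterSpec]] = None,
) -> RadiusProfile:
    """Transform a full parameter set into a radius profile for ``system``."""
    values = params.as_dict()
    wanted = system_parameter_ids(system, registry)
    raw = {pid: radius_value(pid, values[pid], registry) for pid in wanted}
    return RadiusProfile(batch_id=batch_id, system=system, raw=raw)
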