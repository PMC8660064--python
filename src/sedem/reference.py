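"""Bundled reference dataset: a published atenolol high-shear wet-granulation
case study (13-trial design, granule radius values, incidence factors,
suitability indices and tablet QC metrics).

The tables ship as plain CSV inside the package so the full pipeline can be
validated offline. Two ODT cells of the source tables (Trials 9 and 10) are
internally inconsistent with the printed radii — only the effervescence-time
radius appears to have been counted in their Disgregability means — and are
carried as a documented exception list rather than silently "fixed".
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .indices import full_report, incidence_factors
from .radii import SYSTEM_CLASSIC, SYSTEM_ODT, RadiusProfile

#: Centre-point replicates share the radii reported once for Trial-1.
CENTER_TRIAL_ALIASES = {
    "Trial-3": "Trial-1",
    "Trial-4": "Trial-1",
    "Trial-6": "Trial-1",
    "Trial-7": "Trial-1",
}

#: (batch_id, column) cells of the reference tables that do NOT reproduce from
#: the reference radii (see module docstring). Everything else must match.
DOCUMENTED_INDEX_EXCEPTIONS = frozenset(
    {
        ("Trial-9", "IPP_odt"),
        ("Trial-9", "IGCB"),
        ("Trial-10", "IPP_odt"),
        ("Trial-10", "IGCB"),
    }
)
DOCUMENTED_INCIDENCE_EXCEPTIONS = frozenset(
    {
        ("Trial-9", "Disgregability"),
        ("Trial-10", "Disgregability"),
    }
)

#: Comparison tolerance against printed (2-3 decimal) values.
PRINT_TOL = 0.01

#: Punch diameter (mm) used for every trial's tablets.
PUNCH_DIAMETER_MM = 10.5


def _read(name: str) -> pd.DataFrame:
    with resources.files("sedem").joinpath(f"data/{name}").open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class ReferenceBundle:
    """Typed access to every bundled table."""

    design: pd.DataFrame            # 13 runs, coded + actual levels
    powder_radii: pd.DataFrame      # parameter x {Atenolol, Powder Blend}
    trial_radii: pd.DataFrame       # parameter x 9 granulation trials
    incidence: pd.DataFrame         # batch x 6 incidence factors
    indices: pd.DataFrame           # batch x {IP, IPP, IGCB / IP, IPP, IGC}
    tablets: pd.DataFrame           # trial x tablet QC metrics

    def radii_for(self, batch_id: str) -> dict[str, float]:
        """Radius values for a powder, blend or trial (centre aliases resolved)."""
        batch_id = CENTER_TRIAL_ALIASES.get(batch_id, batch_id)
        for table in (self.powder_radii, self.trial_radii):
            if batch_id in table.columns:
                return dict(zip(table["parameter"], table[batch_id].astype(float)))
        raise KeyError(f"no reference radii for batch {batch_id!r}")

    def profile(self, batch_id: str, system: str = SYSTEM_ODT) -> RadiusProfile:
        return RadiusProfile.from_radii(batch_id, self.radii_for(batch_id), system)

    @property
    def radius_batches(self) -> list[str]:
        """Batches with directly reported radii (powders + 9 distinct trials)."""
        return [c for c in self.powder_radii.columns if c != "parameter"] + [
            c for c in self.trial_radii.columns if c != "parameter"
        ]


def load_reference() -> ReferenceBundle:
    return ReferenceBundle(
        design=_read("reference_design.csv"),
        powder_radii=_read("reference_powder_radii.csv"),
        trial_radii=_read("reference_trial_radii.csv"),
        incidence=_read("reference_incidence.csv"),
        indices=_read("reference_indices.csv"),
        tablets=_read("reference_tablets.csv"),
    )


@dataclass(frozen=True)
class CellCheck:
    """Outcome of recomputing one published cell from the reference radii."""

    table: str
    batch_id: str
    column: str
    expected: float
    computed: float
    within_tol: bool
    documented_exception: bool

    @property
    def ok(self) -> bool:
        return self.within_tol or self.documented_exception


def reproduce_reference(bundle: ReferenceBundle | None = None, tol: float = PRINT_TOL) -> list[CellCheck]:
    """Recompute every index/incidence cell from the bundled radii.

    Returns one :class:`CellCheck` per cell; a run is healthy when every check
    has ``ok`` True and the failing cells are exactly the documented ones.
    """
    bundle = bundle or load_reference()
    checks: list[CellCheck] = []

    idx = bundle.indices.set_index("batch_id")
    for batch_id in idx.index:
        radii = bundle.radii_for(batch_id)
        odt = full_report(RadiusProfile.from_radii(batch_id, radii, SYSTEM_ODT))
        classic = full_report(RadiusProfile.from_radii(batch_id, radii, SYSTEM_CLASSIC))
        computed = {
            "IP_odt": odt.ip, "IPP_odt": odt.ipp, "IGCB": odt.igcb,
            "IP_classic": classic.ip, "IPP_classic": classic.ipp, "IGC": classic.igcb,
        }
        for col, value in computed.items():
            expected = float(idx.loc[batch_id, col])
            checks.append(
                CellCheck(
                    table="indices",
                    batch_id=batch_id,
                    column=col,
                    expected=expected,
                    computed=value,
                    within_tol=abs(value - expected) <= tol,
                    documented_exception=(batch_id, col) in DOCUMENTED_INDEX_EXCEPTIONS,
                )
            )

    inc = bundle.incidence.set_index("batch_id")
    for batch_id in inc.index:
        profile = bundle.profile(batch_id, SYSTEM_ODT)
        computed_inc = incidence_factors(profile)
        for col in inc.columns:
            expected = float(inc.loc[batch_id, col])
            value = computed_inc[col]
            checks.append(
                CellCheck(
                    table="incidence",
                    batch_id=batch_id,
                    column=col,
                    expected=expected,
                    computed=value,
                    within_tol=abs(value - expected) <= tol,
                    documented_exception=(batch_id, col) in DOCUMENTED_INCIDENCE_EXCEPTIONS,
                )
            )
    return checks
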