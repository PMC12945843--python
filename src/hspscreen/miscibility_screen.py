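"""Flory-Huggins chi computation and ranked drug-excipient screening.

For a drug-excipient pair the interaction parameter is estimated from the
total solubility parameters as

    chi = Vm * (delta_t_drug - delta_t_excipient)**2 / (R * T)

with Vm the molar volume of the *drug* in cm^3/mol, R = 8.314 J/(mol K) and
T in kelvin (MPa * cm^3 = J keeps chi dimensionless).  chi below 0.5 is
read as thermodynamic miscibility.  Inorganic carriers (mesoporous silica)
fall outside the lattice-mixing picture, so their chi is reported as not
applicable; the Hansen distance Ra still ranks them.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .hsp_core import (
    DEFAULT_THRESHOLDS,
    MiscibilityThresholds,
    RaCategory,
    Role,
    Substance,
    classify_by_ra,
    interaction_radius,
    total_parameter,
)

__all__ = [
    "ChiContext",
    "ChiCategory",
    "PairAssessment",
    "ScreeningReport",
    "flory_huggins_chi",
    "classify_by_chi",
    "assess_pair",
    "screen",
]

GAS_CONSTANT = 8.314  # J/(mol K)


from enum import Enum


class ChiCategory(str, Enum):
    MISCIBLE = "miscible"
    NOT_MISCIBLE = "not_miscible"
    NOT_APPLICABLE = "not_applicable"


@dataclass(frozen=True)
class ChiContext:
    """Physical context for the chi estimate.

    ``drug_molar_volume`` is Vm of the drug in cm^3/mol (typically a Fedors
    group-contribution estimate); temperature defaults to 298 K.
    """

    drug_molar_volume: float
    temperature: float = 298.0
    gas_constant: float = GAS_CONSTANT

    def __post_init__(self) -> None:
        if self.drug_molar_volume is None or self.drug_molar_volume <= 0:
            raise ValueError(
                f"drug_molar_volume must be > 0 cm^3/mol, got {self.drug_molar_volume!r}"
            )
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature!r}")
        if self.gas_constant <= 0:
            raise ValueError(f"gas_constant must be > 0, got {self.gas_constant!r}")


@dataclass(frozen=True)
class PairAssessment:
    """Computed miscibility indicators for one drug-excipient pair."""

    excipient: str
    role: Role
    ra: float
    delta_t_drug: float
    delta_t_excipient: float
    chi: Optional[float]
    ra_class: RaCategory
    chi_class: ChiCategory
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScreeningReport:
    """Ranked assessments for one drug against a set of excipients."""

    drug: str
    context: ChiContext
    thresholds: MiscibilityThresholds
    assessments: tuple[PairAssessment, ...]
    best_per_role: Mapping[str, str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([_row(a) for a in self.assessments])

    def to_csv(self, path=None) -> Optional[str]:
        """Write the report as CSV (columns mirror the two screening tables).

        Floats are rounded to 2 decimals for display; regeneration from the
        same inputs is byte-identical.
        """
        frame = self.to_frame()
        text = frame.to_csv(index=False, lineterminator="\n")
        if path is None:
            return text
        Path(path).write_text(text)
        return None

    def to_markdown(self) -> str:
        buf = io.StringIO()
        t = self.thresholds
        buf.write(f"# Miscibility screen: {self.drug}\n\n")
        buf.write(
            f"Vm(drug) = {self.context.drug_molar_volume:.1f} cm3/mol, "
            f"T = {self.context.temperature:.1f} K; thresholds: "
            f"Ra < {t.ra_miscible:g} miscible, Ra > {t.ra_immiscible:g} "
            f"immiscible, chi < {t.chi_miscible:g} miscible.\n\n"
        )
        buf.write(
            "| excipient | role | Ra | Ra class | delta_t | chi | chi class |\n"
            "|---|---|---|---|---|---|---|\n"
        )
        for a in self.assessments:
            chi = "NA" if a.chi is None else f"{a.chi:.3f}"
            buf.write(
                f"| {a.excipient} | {a.role.value} | {a.ra:.2f} | "
                f"{a.ra_class.value} | {a.delta_t_excipient:.2f} | {chi} | "
                f"{a.chi_class.value} |\n"
            )
        buf.write("\nBest candidate per role (lowest Ra, chi tie-break):\n")
        for role in sorted(self.best_per_role):
            buf.write(f"- {role}: {self.best_per_role[role]}\n")
        notes = [n for a in self.assessments for n in a.notes]
        if notes:
            buf.write("\nNotes:\n")
            for note in notes:
                buf.write(f"- {note}\n")
        return buf.getvalue()


def _row(a: PairAssessment) -> dict:
    return {
        "excipient": a.excipient,
        "role": a.role.value,
        "ra": round(a.ra, 2),
        "ra_class": a.ra_class.value,
        "delta_t_drug": round(a.delta_t_drug, 2),
        "delta_t_excipient": round(a.delta_t_excipient, 2),
        "chi": "NA" if a.chi is None else round(a.chi, 3),
        "chi_class": a.chi_class.value,
        "notes": "; ".join(a.notes),
    }


def flory_huggins_chi(
    drug: Substance, excipient: Substance, context: ChiContext
) -> Optional[float]:
    """chi = Vm (delta_t difference)^2 / RT; None for inorganic carriers."""
    if context is None:
        raise ValueError("a ChiContext with the drug molar volume is required")
    if excipient.inorganic:
        return None
    dt_drug = total_parameter(drug.hsp)
    dt_exc = total_parameter(excipient.hsp)
    rt = context.gas_constant * context.temperature  # J/mol
    return context.drug_molar_volume * (dt_drug - dt_exc) ** 2 / rt


def classify_by_chi(
    chi: Optional[float], thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS
) -> ChiCategory:
    """Classify chi: strictly below the cut-off is miscible; None -> NA."""
    if chi is None:
        return ChiCategory.NOT_APPLICABLE
    if chi < 0 or not math.isfinite(chi):
        raise ValueError(f"chi must be a finite non-negative number, got {chi!r}")
    if chi < thresholds.chi_miscible:
        return ChiCategory.MISCIBLE
    return ChiCategory.NOT_MISCIBLE


def assess_pair(
    drug: Substance,
    excipient: Substance,
    context: ChiContext,
    thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS,
    printed_ra: Optional[float] = None,
    printed_chi: Optional[float] = None,
) -> PairAssessment:
    """Full assessment of one pair: Ra, delta_t, chi and both categories.

    ``printed_ra``/``printed_chi`` are optional literature values attached
    purely for provenance; when a printed value disagrees with the
    recomputed one by more than 0.05 a discrepancy note is recorded.
    """
    if drug.role is not Role.DRUG:
        raise ValueError(f"first substance must have role 'drug', got {drug.role.value!r}")
    ra = interaction_radius(drug.hsp, excipient.hsp)
    chi = flory_huggins_chi(drug, excipient, context)
    notes: list[str] = []
    if printed_ra is not None and abs(printed_ra - ra) > 0.05:
        notes.append(
            f"{excipient.name}: published Ra {printed_ra:.2f} is not reproducible "
            f"from the published Hansen components (recomputed {ra:.2f}); "
            "computed value used"
        )
    if printed_chi is not None and chi is not None and abs(printed_chi - chi) > 0.05:
        notes.append(
            f"{excipient.name}: published chi {printed_chi:.3f} differs from the "
            f"recomputed {chi:.3f}; computed value used"
        )
    return PairAssessment(
        excipient=excipient.name,
        role=excipient.role,
        ra=ra,
        delta_t_drug=total_parameter(drug.hsp),
        delta_t_excipient=total_parameter(excipient.hsp),
        chi=chi,
        ra_class=classify_by_ra(ra, thresholds),
        chi_class=classify_by_chi(chi, thresholds),
        notes=tuple(notes),
    )


def screen(
    drug: Substance,
    excipients: Sequence[Substance],
    context: ChiContext,
    thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS,
    printed_ra: Optional[Mapping[str, float]] = None,
    printed_chi: Optional[Mapping[str, Optional[float]]] = None,
) -> ScreeningReport:
    """Assess every excipient and rank ascending by Ra (chi tie-break).

    ``best_per_role`` picks, for each role present, the excipient with the
    lowest Ra, breaking Ra ties by chi (absent chi sorts last).
    """
    if not excipients:
        raise ValueError("excipient list must be non-empty")
    names = [e.name for e in excipients]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate excipient name(s): {dupes}")
    printed_ra = printed_ra or {}
    printed_chi = printed_chi or {}
    assessments = [
        assess_pair(
            drug,
            excipient,
            context,
            thresholds,
            printed_ra=printed_ra.get(excipient.name),
            printed_chi=printed_chi.get(excipient.name, None),
        )
        for excipient in excipients
    ]

    def sort_key(a: PairAssessment):
        return (a.ra, a.chi if a.chi is not None else math.inf, a.excipient)

    assessments.sort(key=sort_key)
    best_per_role: dict[str, str] = {}
    for a in assessments:  # already sorted: first hit per role wins
        best_per_role.setdefault(a.role.value, a.excipient)
    return ScreeningReport(
        drug=drug.name,
        context=context,
        thresholds=thresholds,
        assessments=tuple(assessments),
        best_per_role=best_per_role,
    )
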