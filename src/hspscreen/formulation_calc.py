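"""Formulation arithmetic: yield, HPLC drug content, equimolar masses, loading.

These are the bookkeeping formulas of a preformulation batch sheet:

* percent yield = 100 * actual dried mass / initial total mass,
* HPLC drug content (%) from sample/standard peak-area and concentration
  ratios,
* equimolar mass conversion for 1:1 molar batching of coformers,
* drug loading (% w/w) of a carrier-based formulation,
* a stoichiometry check reporting the molar ratios actually implied by a
  batch composition next to its nominal recipe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

__all__ = [
    "Composition",
    "HplcMeasurement",
    "percent_yield",
    "drug_content_percent",
    "equimolar_mass",
    "drug_loading_percent",
    "molar_ratios",
]


@dataclass(frozen=True)
class Composition:
    """One formulation's batch composition (component masses in mg)."""

    formulation_id: str
    components: Mapping[str, float]
    drug_component: str

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("composition must list at least one component")
        for name, mass in self.components.items():
            if mass <= 0:
                raise ValueError(
                    f"{self.formulation_id}: mass of {name!r} must be > 0, got {mass!r}"
                )
        if self.drug_component not in self.components:
            raise ValueError(
                f"{self.formulation_id}: drug component {self.drug_component!r} "
                "not present in the composition"
            )

    @property
    def total_mass(self) -> float:
        return float(sum(self.components.values()))

    @property
    def drug_mass(self) -> float:
        return float(self.components[self.drug_component])

    @property
    def excipient_mass(self) -> float:
        return self.total_mass - self.drug_mass


@dataclass(frozen=True)
class HplcMeasurement:
    """Peak areas and concentrations for a single HPLC content assay."""

    sample_peak_area: float
    standard_peak_area: float
    standard_concentration: float  # mg/mL
    nominal_concentration: float  # mg/mL

    def __post_init__(self) -> None:
        for name in (
            "sample_peak_area",
            "standard_peak_area",
            "standard_concentration",
            "nominal_concentration",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")


def percent_yield(actual_mass: float, initial_total_mass: float) -> float:
    """Process yield: 100 * actual dried product mass / initial batch mass.

    Values above 100 % are physically possible (residual solvent/moisture)
    and produce a :class:`UserWarning` rather than an error.
    """
    if actual_mass <= 0:
        raise ValueError(f"actual_mass must be > 0, got {actual_mass!r}")
    if initial_total_mass <= 0:
        raise ValueError(
            f"initial_total_mass must be > 0, got {initial_total_mass!r}"
        )
    result = 100.0 * actual_mass / initial_total_mass
    if result > 100.0:
        warnings.warn(
            f"yield {result:.2f}% exceeds 100%; check for residual solvent "
            "or weighing error",
            UserWarning,
            stacklevel=2,
        )
    return result


def drug_content_percent(m: HplcMeasurement) -> float:
    """HPLC drug content: 100 * (A_sample * C_standard) / (A_standard * C_nominal)."""
    return (
        100.0
        * (m.sample_peak_area * m.standard_concentration)
        / (m.standard_peak_area * m.nominal_concentration)
    )


def equimolar_mass(
    reference_mass: float, reference_molar_mass: float, target_molar_mass: float
) -> float:
    """Mass of the target substance equimolar to ``reference_mass`` of the reference.

    All masses in mg, molar masses in g/mol.
    """
    for name, value in (
        ("reference_mass", reference_mass),
        ("reference_molar_mass", reference_molar_mass),
        ("target_molar_mass", target_molar_mass),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")
    return reference_mass * target_molar_mass / reference_molar_mass


def drug_loading_percent(drug_mass: float, carrier_mass: float) -> float:
    """Drug loading, % w/w: 100 * drug / (drug + carrier)."""
    if drug_mass < 0 or carrier_mass < 0:
        raise ValueError("masses must be non-negative")
    total = drug_mass + carrier_mass
    if total == 0:
        raise ValueError("drug_mass and carrier_mass cannot both be zero")
    return 100.0 * drug_mass / total


def molar_ratios(
    composition: Composition,
    molar_masses: Mapping[str, float],
    exclude: tuple[str, ...] = (),
) -> dict[str, float]:
    """Molar ratios implied by a batch composition, normalised to max = 1.

    Reports what a nominally "1:1:1" recipe actually weighs out; components
    in ``exclude`` (e.g. pH adjusters) are skipped.  Requires a molar mass
    for every included component.
    """
    moles: dict[str, float] = {}
    for name, mass in composition.components.items():
        if name in exclude:
            continue
        mm = molar_masses.get(name)
        if mm is None or mm <= 0:
            raise ValueError(f"molar mass required for component {name!r}")
        moles[name] = mass / mm  # mmol, masses in mg
    reference = max(moles.values())
    return {name: value / reference for name, value in moles.items()}
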