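"""Hansen solubility parameter (HSP) mathematics.

The three-component Hansen decomposition splits the cohesive energy density
of a substance into dispersion (``delta_d``), polar (``delta_p``) and
hydrogen-bonding (``delta_h``) contributions, each in MPa^0.5.  Two
substances that sit close together in Hansen space are expected to mix; the
conventional distance is the interaction radius

    Ra = sqrt(4*(dd1 - dd2)**2 + (dp1 - dp2)**2 + (dh1 - dh2)**2)

with the factor 4 on the dispersion axis.  In amorphous-formulation
screening, pairs with Ra below about 7 MPa^0.5 are treated as miscible and
pairs above about 10 MPa^0.5 as immiscible; the band in between is
borderline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "HSPComponents",
    "Substance",
    "Role",
    "MiscibilityThresholds",
    "RaCategory",
    "DEFAULT_THRESHOLDS",
    "total_parameter",
    "interaction_radius",
    "classify_by_ra",
]


class Role(str, Enum):
    """Functional role of a substance in an amorphous formulation."""

    DRUG = "drug"
    POLYMER = "polymer"
    MESOPOROUS_CARRIER = "mesoporous_carrier"
    COFORMER = "coformer"
    OTHER = "other"


class RaCategory(str, Enum):
    MISCIBLE = "miscible"
    BORDERLINE = "borderline"
    IMMISCIBLE = "immiscible"


@dataclass(frozen=True)
class HSPComponents:
    """A (delta_d, delta_p, delta_h) triple in MPa^0.5."""

    delta_d: float
    delta_p: float
    delta_h: float

    def __post_init__(self) -> None:
        for name in ("delta_d", "delta_p", "delta_h"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value!r}")

    @property
    def total(self) -> float:
        """Total (Hildebrand-equivalent) solubility parameter delta_t."""
        return math.sqrt(self.delta_d**2 + self.delta_p**2 + self.delta_h**2)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.delta_d, self.delta_p, self.delta_h)


@dataclass(frozen=True)
class Substance:
    """A named drug or excipient with its Hansen parameters.

    Parameters
    ----------
    name : str
        Display name, unique within a screening set.
    role : Role or str
        One of drug/polymer/mesoporous_carrier/coformer/other.
    hsp : HSPComponents
        Hansen triple in MPa^0.5.
    molar_volume : float, optional
        Vm in cm^3/mol (group-contribution estimate for small molecules).
    molar_mass : float, optional
        g/mol.
    inorganic : bool
        True for carriers such as mesoporous silica, for which a lattice
        mixing model (and hence the Flory-Huggins chi) is not applicable.
    """

    name: str
    role: Role
    hsp: HSPComponents
    molar_volume: Optional[float] = None
    molar_mass: Optional[float] = None
    inorganic: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("substance name must be non-empty")
        object.__setattr__(self, "role", Role(self.role))
        if self.molar_volume is not None and self.molar_volume <= 0:
            raise ValueError(f"molar_volume must be > 0, got {self.molar_volume!r}")
        if self.molar_mass is not None and self.molar_mass <= 0:
            raise ValueError(f"molar_mass must be > 0, got {self.molar_mass!r}")


@dataclass(frozen=True)
class MiscibilityThresholds:
    """Classification cut-offs for Ra (MPa^0.5) and chi (dimensionless).

    Defaults follow the usual screening convention: Ra below 7 MPa^0.5 is
    miscible, above 10 immiscible, and chi below 0.5 thermodynamically
    miscible.  Both Ra comparisons are strict, so Ra exactly at a cut-off
    falls in the borderline band; chi exactly at the cut-off is classified
    not miscible.
    """

    ra_miscible: float = 7.0
    ra_immiscible: float = 10.0
    chi_miscible: float = 0.5

    def __post_init__(self) -> None:
        if not self.ra_miscible < self.ra_immiscible:
            raise ValueError(
                "ra_miscible must be below ra_immiscible, got "
                f"{self.ra_miscible!r} >= {self.ra_immiscible!r}"
            )
        if self.chi_miscible <= 0:
            raise ValueError(f"chi_miscible must be > 0, got {self.chi_miscible!r}")


DEFAULT_THRESHOLDS = MiscibilityThresholds()


def total_parameter(hsp: HSPComponents) -> float:
    """Total solubility parameter delta_t = sqrt(dd^2 + dp^2 + dh^2)."""
    if not isinstance(hsp, HSPComponents):
        hsp = HSPComponents(*hsp)
    return hsp.total


def interaction_radius(a: HSPComponents, b: HSPComponents) -> float:
    """Hansen interaction radius Ra between two substances, MPa^0.5.

    Ra^2 = 4*(dd_a - dd_b)^2 + (dp_a - dp_b)^2 + (dh_a - dh_b)^2.  The
    result is symmetric in its arguments and zero exactly when the two
    triples coincide.
    """
    if not isinstance(a, HSPComponents):
        a = HSPComponents(*a)
    if not isinstance(b, HSPComponents):
        b = HSPComponents(*b)
    return math.sqrt(
        4.0 * (a.delta_d - b.delta_d) ** 2
        + (a.delta_p - b.delta_p) ** 2
        + (a.delta_h - b.delta_h) ** 2
    )


def classify_by_ra(
    ra: float, thresholds: MiscibilityThresholds = DEFAULT_THRESHOLDS
) -> RaCategory:
    """Classify a Hansen distance into miscible / borderline / immiscible."""
    if ra < 0 or not math.isfinite(ra):
        raise ValueError(f"ra must be a finite non-negative number, got {ra!r}")
    if ra < thresholds.ra_miscible:
        return RaCategory.MISCIBLE
    if ra > thresholds.ra_immiscible:
        return RaCategory.IMMISCIBLE
    return RaCategory.BORDERLINE
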