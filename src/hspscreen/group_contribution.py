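"""Group-contribution estimation of molar volume, HSP components and molar mass.

Two classical increment schemes are bundled:

* Fedors volume increments give the molar volume Vm as a plain sum of
  per-group contributions ``delta_v`` (cm^3/mol); several increments are
  negative (branching carbons), so only the *total* is required to be
  positive.
* Hoftyzer-Van Krevelen molar attraction constants give the Hansen
  components from a fragment multiset and a molar volume V:

      delta_d = sum(n_i * Fd_i) / V
      delta_p = sqrt(sum(n_i * Fp_i**2)) / V
      delta_h = sqrt(sum(n_i * Eh_i) / V)

  with Fd, Fp in MPa^0.5 cm^3/mol and Eh in J/mol.

The supported primary input is a user-supplied fragment multiset
(:class:`FragmentCounts`); :func:`decompose_structure` is an optional
convenience that derives one from a SMILES string via SMARTS matching and
requires rdkit.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Union

import pandas as pd

from .hsp_core import HSPComponents

__all__ = [
    "FragmentCounts",
    "GroupContributionTable",
    "UnknownGroupError",
    "CoverageError",
    "UnsupportedSubstanceError",
    "load_group_table",
    "fedors_molar_volume",
    "hvk_hsp",
    "decompose_structure",
    "molar_mass",
    "parse_formula",
    "ATOMIC_WEIGHTS",
]


class UnknownGroupError(KeyError):
    """A fragment label is absent from the active group-contribution table."""


class CoverageError(ValueError):
    """A structure contains atoms not covered by any group pattern."""


class UnsupportedSubstanceError(ValueError):
    """The substance is outside the scheme's domain (e.g. inorganic)."""


# IUPAC 2021 standard atomic weights, rounded to 3 decimals.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Br": 79.904,
    "I": 126.904,
}

_ORGANIC_ELEMENTS = {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}


FragmentCountsLike = Union["FragmentCounts", Mapping[str, int]]


@dataclass(frozen=True)
class FragmentCounts:
    """Multiset of functional-group labels with occurrence counts."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        cleaned: dict[str, int] = {}
        for label, count in self.counts.items():
            if int(count) != count or count < 0:
                raise ValueError(
                    f"count for group {label!r} must be a non-negative integer, "
                    f"got {count!r}"
                )
            if count > 0:
                cleaned[str(label)] = int(count)
        object.__setattr__(self, "counts", cleaned)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def items(self):
        return self.counts.items()

    def union(self, other: FragmentCountsLike) -> "FragmentCounts":
        """Multiset (disjoint) union: counts add."""
        other = as_fragment_counts(other)
        merged = dict(self.counts)
        for label, count in other.items():
            merged[label] = merged.get(label, 0) + count
        return FragmentCounts(merged)

    def scaled(self, factor: int) -> "FragmentCounts":
        return FragmentCounts({k: v * factor for k, v in self.counts.items()})


def as_fragment_counts(fragments: FragmentCountsLike) -> FragmentCounts:
    if isinstance(fragments, FragmentCounts):
        return fragments
    return FragmentCounts(dict(fragments))


@dataclass(frozen=True)
class GroupIncrements:
    """Per-group increments: HVK molar attractions plus a Fedors volume."""

    Fd: float  # MPa^0.5 cm^3/mol
    Fp: float  # MPa^0.5 cm^3/mol
    Eh: float  # J/mol
    delta_v: float  # cm^3/mol (Fedors; may be negative for branch carbons)
    smarts: Optional[str] = None
    priority: int = 0


@dataclass(frozen=True)
class GroupContributionTable:
    """Named increment table mapping group labels to their contributions."""

    groups: Mapping[str, GroupIncrements]
    scheme: str = "hvk-fedors"
    citation: str = (
        "Hoftyzer & Van Krevelen molar attraction constants (Properties of "
        "Polymers, 4th ed., 2009) with Fedors (1974) volume increments"
    )

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("group-contribution table must be non-empty")

    def __contains__(self, label: str) -> bool:
        return label in self.groups

    def __getitem__(self, label: str) -> GroupIncrements:
        try:
            return self.groups[label]
        except KeyError:
            raise UnknownGroupError(
                f"group {label!r} is not in the {self.scheme!r} table"
            ) from None

    @property
    def labels(self) -> list[str]:
        return list(self.groups)

    @classmethod
    def from_csv(cls, path, scheme: str = "hvk-fedors") -> "GroupContributionTable":
        frame = pd.read_csv(path)
        groups: dict[str, GroupIncrements] = {}
        for row in frame.itertuples(index=False):
            label = str(row.label)
            if label in groups:
                raise ValueError(f"duplicate group label {label!r} in {path}")
            smarts = None if pd.isna(row.smarts) else str(row.smarts)
            groups[label] = GroupIncrements(
                Fd=float(row.Fd),
                Fp=float(row.Fp),
                Eh=float(row.Eh),
                delta_v=float(row.delta_v),
                smarts=smarts,
                priority=int(row.priority),
            )
        return cls(groups=groups, scheme=scheme)


_SCHEMES = {"hvk-fedors": "group_contributions.csv"}
_TABLE_CACHE: dict[str, GroupContributionTable] = {}


def load_group_table(scheme: str = "hvk-fedors") -> GroupContributionTable:
    """Load a bundled increment table by scheme name."""
    if scheme not in _SCHEMES:
        raise ValueError(
            f"unknown group-contribution scheme {scheme!r}; "
            f"available: {sorted(_SCHEMES)}"
        )
    if scheme not in _TABLE_CACHE:
        ref = resources.files("hspscreen.data").joinpath(_SCHEMES[scheme])
        with resources.as_file(ref) as path:
            _TABLE_CACHE[scheme] = GroupContributionTable.from_csv(path, scheme=scheme)
    return _TABLE_CACHE[scheme]


def _resolve(fragments: FragmentCountsLike, table: GroupContributionTable):
    fragments = as_fragment_counts(fragments)
    if not fragments:
        raise ValueError("fragment set must contain at least one group")
    return [(table[label], count) for label, count in fragments.items()]


def fedors_molar_volume(
    fragments: FragmentCountsLike, table: Optional[GroupContributionTable] = None
) -> float:
    """Fedors molar volume: Vm = sum(n_i * delta_v_i), cm^3/mol."""
    table = table or load_group_table()
    volume = sum(inc.delta_v * count for inc, count in _resolve(fragments, table))
    if volume <= 0:
        raise ValueError(
            f"fragment set sums to a non-positive molar volume ({volume:.2f} "
            "cm^3/mol); the multiset is not a plausible molecule"
        )
    return volume


def hvk_hsp(
    fragments: FragmentCountsLike,
    table: Optional[GroupContributionTable] = None,
    molar_volume: Optional[float] = None,
) -> HSPComponents:
    """Hoftyzer-Van Krevelen Hansen components from a fragment multiset.

    If ``molar_volume`` is omitted it is estimated from the same fragments
    via :func:`fedors_molar_volume`.
    """
    table = table or load_group_table()
    if molar_volume is None:
        molar_volume = fedors_molar_volume(fragments, table)
    if molar_volume <= 0:
        raise ValueError(f"molar_volume must be > 0, got {molar_volume!r}")
    resolved = _resolve(fragments, table)
    fd_sum = sum(inc.Fd * count for inc, count in resolved)
    fp_sq_sum = sum(count * inc.Fp**2 for inc, count in resolved)
    eh_sum = sum(inc.Eh * count for inc, count in resolved)
    if fd_sum < 0:
        raise ValueError("dispersion attraction sum is negative; invalid multiset")
    if eh_sum < 0:
        raise ValueError("hydrogen-bond energy sum is negative; invalid multiset")
    return HSPComponents(
        delta_d=fd_sum / molar_volume,
        delta_p=math.sqrt(fp_sq_sum) / molar_volume,
        delta_h=math.sqrt(eh_sum / molar_volume),
    )


def decompose_structure(
    structure: str, table: Optional[GroupContributionTable] = None
) -> FragmentCounts:
    """Decompose a SMILES string into table fragments (requires rdkit).

    Patterns are applied in ascending priority order (most specific first);
    each heavy atom is claimed by exactly one match, first match wins.  Ring
    closures are counted separately (one ``ring34``/``ring5plus`` per SSSR
    ring) and consume no atoms.
    """
    from rdkit import Chem  # deliberate lazy import: optional dependency

    table = table or load_group_table()
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"could not parse structure string {structure!r}")

    symbols = {atom.GetSymbol() for atom in mol.GetAtoms()}
    foreign = symbols - _ORGANIC_ELEMENTS
    if foreign:
        raise UnsupportedSubstanceError(
            f"structure contains non-organic element(s) {sorted(foreign)}; "
            "group-contribution schemes cover organic molecules only"
        )

    counts: dict[str, int] = {}
    claimed: set[int] = set()
    patterned = sorted(
        ((label, inc) for label, inc in table.groups.items() if inc.smarts),
        key=lambda item: item[1].priority,
    )
    for label, inc in patterned:
        pattern = Chem.MolFromSmarts(inc.smarts)
        if pattern is None:  # defensive: bundled patterns are pre-validated
            raise ValueError(f"invalid SMARTS for group {label!r}: {inc.smarts!r}")
        for match in mol.GetSubstructMatches(pattern):
            atoms = set(match)
            if atoms & claimed:
                continue
            claimed |= atoms
            counts[label] = counts.get(label, 0) + 1

    unclaimed = [
        f"{atom.GetSymbol()}(idx {atom.GetIdx()}, {atom.GetTotalNumHs()}H)"
        for atom in mol.GetAtoms()
        if atom.GetIdx() not in claimed
    ]
    if unclaimed:
        raise CoverageError(
            "no group pattern covers atom(s): " + ", ".join(unclaimed)
        )

    for ring in mol.GetRingInfo().AtomRings():
        label = "ring34" if len(ring) <= 4 else "ring5plus"
        counts[label] = counts.get(label, 0) + 1

    return FragmentCounts(counts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula like ``C14H13N5O5S2``."""
    if not formula or not formula.strip():
        raise ValueError("molecular formula must be non-empty")
    pos = 0
    atoms: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(formula.strip()):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} near position {pos}")
        pos = match.end()
        element, digits = match.groups()
        count = int(digits) if digits else 1
        if count <= 0:
            raise ValueError(f"atom count must be positive in {formula!r}")
        atoms[element] = atoms.get(element, 0) + count
    if pos != len(formula.strip()) or not atoms:
        raise ValueError(f"malformed formula {formula!r}")
    return atoms


def molar_mass(formula: Union[str, Mapping[str, int]]) -> float:
    """Molar mass in g/mol from a Hill formula or element->count mapping."""
    atoms = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    mass = 0.0
    for element, count in atoms.items():
        try:
            weight = ATOMIC_WEIGHTS[element]
        except KeyError:
            raise UnknownGroupError(
                f"element {element!r} is not in the bundled atomic-weight table"
            ) from None
        mass += weight * count
    return mass
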