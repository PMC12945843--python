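"""Bundled reference fixtures and synthetic substance generation.

The bundled fixture carries the published screening inputs for the cefdinir
case study: the drug plus seven candidate stabilisers (three polymers, the
mesoporous silica SBA-15, and three amino-acid coformers) with their Hansen
components, and the batch compositions of the three prepared formulations.

The fixture also stores the Ra and chi values printed in the source tables.
Those printed values cannot be regenerated from the printed Hansen
components under the stated equations (e.g. cefdinir-PVP K30 recomputes to
Ra = 2.56 MPa^0.5 against a printed 4.11, and the printed chi values imply
mutually inconsistent drug molar volumes), so they are retained strictly as
documentation and never used as computation inputs; screening reports flag
the discrepancy.

The synthetic generator draws substances uniformly over the envelope the
reference excipients span (delta_d 15-19, delta_p 3-15, delta_h 7-18
MPa^0.5) so every downstream stage can be exercised at scale without any
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .group_contribution import (
    FragmentCounts,
    GroupContributionTable,
    fedors_molar_volume,
    load_group_table,
)
from .hsp_core import HSPComponents, Role, Substance

__all__ = [
    "ReferenceFixture",
    "SyntheticSpec",
    "CEFDINIR_SMILES",
    "CEFDINIR_FRAGMENTS",
    "cefdinir_molar_volume",
    "load_reference_substances",
    "generate_synthetic_excipients",
    "generate_synthetic_fragments",
]

#: Cefdinir, C14H13N5O5S2 (395.41 g/mol): a third-generation cephalosporin
#: bearing an aminothiazolyl hydroxyimino side chain, a beta-lactam fused to
#: a dihydrothiazine ring, a carboxylic acid and a vinyl substituent.
CEFDINIR_SMILES = r"NC1=NC(=CS1)/C(=N\O)C(=O)N[C@H]1[C@H]2SCC(=C(N2C1=O)C(O)=O)C=C"

#: Manual decomposition of cefdinir over the bundled hvk-fedors table.
#: Amides are split as CO + NH (secondary) / CO + N (the beta-lactam ring
#: nitrogen); ring closures: thiazole and dihydrothiazine (5+-membered),
#: beta-lactam (4-membered).  Fedors sum: 200.9 cm^3/mol.
CEFDINIR_FRAGMENTS = FragmentCounts(
    {
        "S": 2,
        "C=": 5,
        "CH=": 2,
        "CH2=": 1,
        "N=": 2,
        "NH2": 1,
        "OH": 1,
        "CO": 2,
        "NH": 1,
        "N": 1,
        "CH": 2,
        "CH2": 1,
        "COOH": 1,
        "ring5plus": 2,
        "ring34": 1,
    }
)


def cefdinir_molar_volume(table: Optional[GroupContributionTable] = None) -> float:
    """Fedors molar volume of cefdinir from the bundled decomposition."""
    return fedors_molar_volume(CEFDINIR_FRAGMENTS, table or load_group_table())


_SUBSTANCES_FILE = "substances.csv"
_COMPOSITIONS_FILE = "compositions.yaml"


@dataclass(frozen=True)
class ReferenceFixture:
    """The published screening inputs plus documentation-only printed values."""

    substances: list[Substance]
    compositions: Mapping[str, Mapping[str, float]]
    drug_components: Mapping[str, str]
    printed_ra: Mapping[str, float]
    printed_chi: Mapping[str, Optional[float]]

    @property
    def drug(self) -> Substance:
        (drug,) = [s for s in self.substances if s.role is Role.DRUG]
        return drug

    @property
    def excipients(self) -> list[Substance]:
        return [s for s in self.substances if s.role is not Role.DRUG]

    def substance(self, name: str) -> Substance:
        for s in self.substances:
            if s.name == name:
                return s
        raise KeyError(f"no substance named {name!r} in the fixture")

    # -- serialisation ---------------------------------------------------

    def to_files(self, directory) -> tuple[Path, Path]:
        """Write the fixture back out as substances.csv + compositions.yaml."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        sub_path = directory / _SUBSTANCES_FILE
        comp_path = directory / _COMPOSITIONS_FILE
        rows = []
        for s in self.substances:
            chi = self.printed_chi.get(s.name, None)
            rows.append(
                {
                    "name": s.name,
                    "role": s.role.value,
                    "delta_d": s.hsp.delta_d,
                    "delta_p": s.hsp.delta_p,
                    "delta_h": s.hsp.delta_h,
                    "inorganic": s.inorganic,
                    "molar_mass": "" if s.molar_mass is None else s.molar_mass,
                    "printed_ra": self.printed_ra.get(s.name, ""),
                    "printed_chi": "NA" if (s.name in self.printed_chi and chi is None) else (chi if chi is not None else ""),
                }
            )
        pd.DataFrame(rows).to_csv(sub_path, index=False)
        payload = {
            fid: {
                "drug": self.drug_components[fid],
                "components": {k: float(v) for k, v in comps.items()},
            }
            for fid, comps in self.compositions.items()
        }
        comp_path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return sub_path, comp_path

    @classmethod
    def from_files(cls, substances_path, compositions_path) -> "ReferenceFixture":
        substances_path = Path(substances_path)
        compositions_path = Path(compositions_path)
        for path in (substances_path, compositions_path):
            if not path.exists():
                raise FileNotFoundError(f"fixture file missing: {path}")
        try:
            # keep_default_na: the literal "NA" marks a not-applicable printed
            # chi and must survive parsing
            frame = pd.read_csv(substances_path, keep_default_na=False)
        except Exception as exc:  # pragma: no cover - corrupt file path
            raise ValueError(f"corrupt fixture file {substances_path}: {exc}") from exc
        required = {"name", "role", "delta_d", "delta_p", "delta_h", "inorganic"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(
                f"fixture {substances_path} lacks column(s) {sorted(missing)}"
            )

        substances: list[Substance] = []
        printed_ra: dict[str, float] = {}
        printed_chi: dict[str, Optional[float]] = {}
        def _blank(value) -> bool:
            return value is None or str(value).strip() == "" or pd.isna(value)

        for row in frame.itertuples(index=False):
            molar_mass = getattr(row, "molar_mass", None)
            molar_mass = None if _blank(molar_mass) else float(molar_mass)
            substances.append(
                Substance(
                    name=str(row.name),
                    role=Role(str(row.role)),
                    hsp=HSPComponents(
                        float(row.delta_d), float(row.delta_p), float(row.delta_h)
                    ),
                    molar_mass=molar_mass,
                    inorganic=_as_bool(row.inorganic),
                )
            )
            ra = getattr(row, "printed_ra", None)
            if not _blank(ra):
                printed_ra[str(row.name)] = float(ra)
            chi = getattr(row, "printed_chi", None)
            if not _blank(chi):
                printed_chi[str(row.name)] = None if str(chi) == "NA" else float(chi)

        raw = yaml.safe_load(compositions_path.read_text())
        if not isinstance(raw, dict) or not raw:
            raise ValueError(f"corrupt compositions fixture {compositions_path}")
        compositions: dict[str, dict[str, float]] = {}
        drug_components: dict[str, str] = {}
        for fid, entry in raw.items():
            comps = {str(k): float(v) for k, v in entry["components"].items()}
            for name, mass in comps.items():
                if mass <= 0:
                    raise ValueError(
                        f"composition {fid}: mass of {name!r} must be > 0"
                    )
            compositions[str(fid)] = comps
            drug_components[str(fid)] = str(entry["drug"])

        fixture = cls(
            substances=substances,
            compositions=compositions,
            drug_components=drug_components,
            printed_ra=printed_ra,
            printed_chi=printed_chi,
        )
        fixture.drug  # validates exactly one drug
        return fixture


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def load_reference_substances() -> ReferenceFixture:
    """Load the bundled cefdinir screening fixture."""
    data = resources.files("hspscreen.data")
    with resources.as_file(data.joinpath(_SUBSTANCES_FILE)) as sub_path, resources.as_file(
        data.joinpath(_COMPOSITIONS_FILE)
    ) as comp_path:
        return ReferenceFixture.from_files(sub_path, comp_path)


# ---------------------------------------------------------------------------
# synthetic generation
# ---------------------------------------------------------------------------

_DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "delta_d": (15.0, 19.0),
    "delta_p": (3.0, 15.0),
    "delta_h": (7.0, 18.0),
}

_DEFAULT_ROLE_MIX: dict[str, float] = {
    "polymer": 0.4,
    "coformer": 0.4,
    "mesoporous_carrier": 0.2,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a reproducible batch of synthetic excipients.

    Component ranges default to the envelope spanned by the reference
    excipients; role proportions default to 40 % polymers, 40 % coformers,
    20 % inorganic mesoporous carriers.
    """

    n: int
    seed: int = 0
    ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RANGES)
    )
    role_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_ROLE_MIX)
    )

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError(f"n must be non-negative, got {self.n!r}")
        for key, (low, high) in self.ranges.items():
            if not low < high:
                raise ValueError(f"range for {key!r} must satisfy low < high")
            if low < 0:
                raise ValueError(f"range for {key!r} must be non-negative")
        total = sum(self.role_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"role_mix proportions must sum to 1, got {total!r}")


def generate_synthetic_excipients(spec: SyntheticSpec) -> list[Substance]:
    """Draw ``spec.n`` synthetic excipients, reproducibly by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    roles = sorted(spec.role_mix)
    probs = np.array([spec.role_mix[r] for r in roles])
    out: list[Substance] = []
    for i in range(spec.n):
        hsp = HSPComponents(
            *(
                float(rng.uniform(*spec.ranges[key]))
                for key in ("delta_d", "delta_p", "delta_h")
            )
        )
        role = Role(str(rng.choice(roles, p=probs)))
        inorganic = role is Role.MESOPOROUS_CARRIER
        out.append(
            Substance(
                name=f"synthetic-{spec.seed}-{i:04d}",
                role=role,
                hsp=hsp,
                molar_volume=None if inorganic else float(rng.uniform(80.0, 500.0)),
                inorganic=inorganic,
            )
        )
    return out


def generate_synthetic_fragments(
    seed: int, table: Optional[GroupContributionTable] = None
) -> FragmentCounts:
    """Draw a random, non-empty fragment multiset over the table's labels."""
    table = table or load_group_table()
    labels = [label for label, inc in table.groups.items() if inc.smarts]
    if not labels:
        raise ValueError("group-contribution table has no fragment groups")
    rng = np.random.default_rng(seed)
    k = int(rng.integers(1, min(6, len(labels)) + 1))
    chosen = rng.choice(labels, size=k, replace=False)
    counts = {str(label): int(rng.integers(1, 5)) for label in chosen}
    # guarantee a physically plausible (positive-volume) multiset by always
    # anchoring on a methylene backbone contribution large enough to outweigh
    # the worst-case draw of negative branch-carbon increments
    counts["CH2"] = counts.get("CH2", 0) + 3 * k
    return FragmentCounts(counts)
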