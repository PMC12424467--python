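"""Physicochemical descriptors, elemental mass defects, and the 13-slot feature vector.

The model matrix has a fixed column order, defined once in :func:`feature_names`:

    mw, xlogp, tpsa, hbd, hba, emd_<u1> .. emd_<u6>, mobility_class, log_ie

Mass-defect base units default to CH2, CO, CCl, CN, CF2 and CS but are fully
configurable. Unit labels are read literally as atom groups (``CCl`` = one
carbon plus one chlorine-35).
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

#: donor atoms: N/O/S carrying at least one hydrogen (atom count, so water = 1)
_HBD_SMARTS = Chem.MolFromSmarts("[$([N;!H0]),$([O;!H0]),$([S;!H0])]")

from .errors import AssemblyError, DomainError, SmilesParseError
from .io import CompoundRecord

RDLogger.DisableLog("rdApp.*")

DEFAULT_EMD_UNIT_LABELS = ("CH2", "CO", "CCl", "CN", "CF2", "CS")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def atomic_mass_table() -> dict[str, dict[str, float]]:
    """Embedded monoisotopic mass / mass-number table (symbol -> {mass, number})."""
    text = resources.files("mclspace.data").joinpath("atomic_masses.json").read_text()
    table = json.loads(text)
    table.pop("_comment", None)
    return table


_MASSES = atomic_mass_table()


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula (no charges, no isotope labels)."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"unparseable formula {formula!r} at position {pos}")
        symbol, digits = match.groups()
        if symbol not in _MASSES:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
        pos = match.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"unparseable formula {formula!r}")
    return counts


def formula_monoisotopic_mass(formula: str) -> float:
    """Exact mass of a formula by direct summation over the embedded table."""
    return sum(_MASSES[el]["mass"] * n for el, n in parse_formula(formula).items())


def formula_nominal_mass(formula: str) -> int:
    """Integer (mass-number) mass of a formula."""
    return sum(_MASSES[el]["number"] * n for el, n in parse_formula(formula).items())


@dataclass(frozen=True)
class EMDUnit:
    """A mass-defect base unit, e.g. CH2 (exact 14.01565, nominal 14)."""

    label: str
    exact_mass: float
    nominal_mass: int

    def __post_init__(self):
        if self.exact_mass <= 0:
            raise ValueError("exact_mass must be positive")
        if self.nominal_mass <= 0:
            raise ValueError("nominal_mass must be positive")

    @classmethod
    def from_label(cls, label: str) -> "EMDUnit":
        return cls(
            label=label,
            exact_mass=formula_monoisotopic_mass(label),
            nominal_mass=formula_nominal_mass(label),
        )


def default_emd_units() -> tuple[EMDUnit, ...]:
    return tuple(EMDUnit.from_label(lbl) for lbl in DEFAULT_EMD_UNIT_LABELS)


def elemental_mass_defect(mass: float, unit: EMDUnit) -> float:
    """Kendrick-style mass defect of `mass` relative to `unit`.

    The mass is rescaled by nominal/exact of the unit and the defect is the
    signed distance to the nearest integer, ``n - scaled`` with
    ``n = floor(scaled + 0.5)``, so the result lies in (-0.5, 0.5].
    """
    if not math.isfinite(mass) or mass <= 0:
        raise DomainError(f"mass must be positive and finite, got {mass}")
    scaled = mass * unit.nominal_mass / unit.exact_mass
    return math.floor(scaled + 0.5) - scaled


@dataclass(frozen=True)
class PhyschemDescriptors:
    """The five scalar physicochemical variables of the model.

    ``provenance`` records, per field, whether the value came from the input
    table (``precomputed``) or was computed from the structure (``toolkit``;
    logP additionally tagged ``toolkit-crippen`` because it is a Crippen
    estimate, not XLogP).
    """

    mw: float
    xlogp: float
    tpsa: float
    hbd: int
    hba: int
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.mw <= 0:
            raise ValueError("mw must be positive")
        if self.tpsa < 0:
            raise ValueError("tpsa must be non-negative")
        if self.hbd < 0 or self.hba < 0:
            raise ValueError("hbd/hba must be non-negative")


def mol_from_record(record: CompoundRecord) -> Chem.Mol:
    mol = Chem.MolFromSmiles(record.smiles)
    if mol is None:
        raise SmilesParseError(record.id, record.smiles)
    return mol


def compute_physchem(record: CompoundRecord) -> PhyschemDescriptors:
    """Resolve mw/xlogp/tpsa/hbd/hba for one record.

    Precomputed values from the input table take precedence field by field;
    anything absent is computed from the parsed structure: monoisotopic mass,
    Crippen logP as the XLogP stand-in (flagged in provenance), topological
    PSA, and atom-count H-bond features approximating the PubChem convention
    (donors = N/O/S atoms bearing H, so water counts 1; acceptors = N/O atom
    count).
    """
    pre = record.precomputed
    needed = [f for f in ("mw", "xlogp", "tpsa", "hbd", "hba") if f not in pre]
    computed: dict[str, float] = {}
    if needed:
        mol = mol_from_record(record)
        computed = {
            "mw": Descriptors.ExactMolWt(mol),
            "xlogp": Crippen.MolLogP(mol),
            "tpsa": rdMolDescriptors.CalcTPSA(mol),
            "hbd": len(mol.GetSubstructMatches(_HBD_SMARTS)),
            "hba": Lipinski.NOCount(mol),
        }

    def resolve(name: str):
        if name in pre:
            return pre[name], "precomputed"
        source = "toolkit-crippen" if name == "xlogp" else "toolkit"
        return computed[name], source

    values = {}
    provenance = {}
    for name in ("mw", "xlogp", "tpsa", "hbd", "hba"):
        values[name], provenance[name] = resolve(name)
    return PhyschemDescriptors(
        mw=float(values["mw"]),
        xlogp=float(values["xlogp"]),
        tpsa=float(values["tpsa"]),
        hbd=int(values["hbd"]),
        hba=int(values["hba"]),
        provenance=provenance,
    )


def compute_emds(mass: float, units: Sequence[EMDUnit]) -> dict[str, float]:
    """Mass defects of `mass` for every base unit, keyed by unit label."""
    return {u.label: elemental_mass_defect(mass, u) for u in units}


def feature_names(units: Sequence[EMDUnit] | None = None) -> list[str]:
    """The fixed 13-column order of the model matrix."""
    units = default_emd_units() if units is None else tuple(units)
    if len(units) != 6:
        raise ValueError(f"expected 6 mass-defect units, got {len(units)}")
    return (
        ["mw", "xlogp", "tpsa", "hbd", "hba"]
        + [f"emd_{u.label}" for u in units]
        + ["mobility_class", "log_ie"]
    )


@dataclass(frozen=True)
class FeatureVector:
    """One compound's 13 model variables, in the fixed order of feature_names()."""

    names: tuple[str, ...]
    values: tuple[float, ...]

    def __post_init__(self):
        if len(self.names) != 13 or len(self.values) != 13:
            raise ValueError("feature vector must have exactly 13 slots")
        if any(not math.isfinite(v) for v in self.values):
            raise ValueError("feature values must be finite")
        if self.values[11] not in (1.0, 2.0, 3.0):
            raise ValueError("mobility_class slot must be 1, 2 or 3")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def assemble_features(
    record_id: str,
    physchem: PhyschemDescriptors,
    emds: Mapping[str, float],
    mobility_class: int,
    log_ie: float,
    units: Sequence[EMDUnit] | None = None,
) -> FeatureVector:
    """Place all inputs into the fixed 13-slot order.

    `emds` is keyed by unit label, so caller-side ordering is irrelevant.
    Raises AssemblyError naming the slot and record id on any missing value.
    """
    units = default_emd_units() if units is None else tuple(units)
    names = feature_names(units)
    if mobility_class not in (1, 2, 3):
        raise AssemblyError(
            f"record {record_id!r}: mobility_class must be 1/2/3, got {mobility_class!r}"
        )
    slots: dict[str, float] = {
        "mw": physchem.mw,
        "xlogp": physchem.xlogp,
        "tpsa": physchem.tpsa,
        "hbd": float(physchem.hbd),
        "hba": float(physchem.hba),
        "mobility_class": float(mobility_class),
        "log_ie": float(log_ie),
    }
    for unit in units:
        if unit.label not in emds:
            raise AssemblyError(
                f"record {record_id!r}: missing mass-defect slot emd_{unit.label}"
            )
        slots[f"emd_{unit.label}"] = float(emds[unit.label])
    values = []
    for name in names:
        if name not in slots or not math.isfinite(slots[name]):
            raise AssemblyError(f"record {record_id!r}: missing or non-finite slot {name}")
        values.append(slots[name])
    return FeatureVector(names=tuple(names), values=tuple(values))


def units_from_labels(labels: Iterable[str]) -> tuple[EMDUnit, ...]:
    return tuple(EMDUnit.from_label(lbl) for lbl in labels)
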