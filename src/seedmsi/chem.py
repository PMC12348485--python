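"""Molecular formulas, monoisotopic masses and adduct m/z arithmetic.

This module is the computational core of accurate-mass annotation: it parses
molecular formulas, computes monoisotopic masses from a fixed IUPAC/CODATA
table, applies adduct arithmetic (including the electron mass correction for
charged species) and materializes a sorted, binary-searchable ion index over
a compound library.
"""

from __future__ import annotations

import bisect
import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "FormulaError",
    "ChemicalFormula",
    "CompoundRecord",
    "AdductSpec",
    "IonCandidate",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "neutral_mass_from_mz",
    "build_ion_index",
    "candidates_in_window",
    "default_adducts",
    "load_adducts",
    "load_library",
    "bundled_library",
    "bundled_library_path",
]

# Monoisotopic atomic masses in Da (IUPAC), restricted to the element set
# supported by the library format.  Electron/proton masses from CODATA.
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.000000,
    "H": 1.00782503,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054858
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Raised for malformed or unsupported molecular formulas."""


@dataclass(frozen=True)
class ChemicalFormula:
    """An elemental composition; the empty composition is the null formula."""

    element_counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        for element, count in counts.items():
            if element not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(count, int) or count < 1:
                raise FormulaError(
                    f"count for {element!r} must be a positive integer, got {count!r}"
                )
        object.__setattr__(self, "element_counts", counts)

    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.element_counts)
        for element, count in other.element_counts.items():
            merged[element] = merged.get(element, 0) + count
        return ChemicalFormula(merged)

    def __bool__(self) -> bool:
        return bool(self.element_counts)

    def __str__(self) -> str:
        # Hill order: C, H, then alphabetical.
        elements = sorted(
            self.element_counts,
            key=lambda e: (e != "C", e != "H", e),
        )
        return "".join(
            f"{e}{self.element_counts[e]}" if self.element_counts[e] != 1 else e
            for e in elements
        )


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a molecular formula string such as ``"C27H30O16"``.

    Any element order is accepted; implicit counts expand to 1.  Parentheses,
    hydrates and isotope labels are not supported.
    """
    if not isinstance(text, str) or not text:
        raise FormulaError("formula string must be non-empty")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        match = _TOKEN.match(text, pos)
        if match is None or match.start() != pos or not match.group(1):
            raise FormulaError(f"malformed token at {text[pos:]!r} in {text!r}")
        element, digits = match.groups()
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element symbol {element!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"zero count for {element!r} in {text!r}")
        counts[element] = counts.get(element, 0) + count
        pos = match.end()
    return ChemicalFormula(counts)


def monoisotopic_mass(formula: ChemicalFormula) -> float:
    """Sum of count x monoisotopic atomic mass over the formula's elements."""
    return sum(
        count * MONOISOTOPIC_MASS[element]
        for element, count in formula.element_counts.items()
    )


@dataclass(frozen=True)
class CompoundRecord:
    compound_id: str
    name: str
    formula: ChemicalFormula
    metabolite_class: str
    smiles: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")
        if not self.formula:
            raise ValueError(f"compound {self.compound_id!r} has a null formula")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ion species formed from a neutral molecule M."""

    label: str
    polarity: str
    atoms_added: ChemicalFormula = field(default_factory=ChemicalFormula)
    atoms_removed: ChemicalFormula = field(default_factory=ChemicalFormula)
    charge: int = 1

    def __post_init__(self) -> None:
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")
        if self.charge not in (1, -1):
            raise ValueError("only singly charged species are modeled (|charge| = 1)")
        if (self.charge > 0) != (self.polarity == "positive"):
            raise ValueError(f"charge sign of {self.label!r} contradicts its polarity")

    @property
    def mass_shift(self) -> float:
        """m/z offset relative to the neutral monoisotopic mass."""
        return (
            monoisotopic_mass(self.atoms_added)
            - monoisotopic_mass(self.atoms_removed)
            - self.charge * ELECTRON_MASS
        )


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """m/z of the adduct ion of a neutral molecule of the given mass."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    mz = neutral_mass + adduct.mass_shift
    if mz <= 0:
        raise ValueError(
            f"adduct {adduct.label!r} applied to mass {neutral_mass} gives non-positive m/z"
        )
    return mz


def neutral_mass_from_mz(mz: float, adduct: AdductSpec) -> float:
    """Exact inverse of :func:`adduct_mz`."""
    if mz <= 0:
        raise ValueError("m/z must be positive")
    mass = mz - adduct.mass_shift
    if mass < 0:
        raise ValueError(
            f"m/z {mz} as {adduct.label!r} implies a negative neutral mass ({mass:.4f})"
        )
    return mass


def _default_adduct_set() -> list[AdductSpec]:
    h = ChemicalFormula({"H": 1})
    return [
        AdductSpec("[M+H]+", "positive", atoms_added=h, charge=1),
        AdductSpec("[M+Na]+", "positive", atoms_added=ChemicalFormula({"Na": 1}), charge=1),
        AdductSpec("[M+K]+", "positive", atoms_added=ChemicalFormula({"K": 1}), charge=1),
        AdductSpec("[M-H]-", "negative", atoms_removed=h, charge=-1),
        AdductSpec("[M+Cl]-", "negative", atoms_added=ChemicalFormula({"Cl": 1}), charge=-1),
        AdductSpec(
            "[M+HCOO]-",
            "negative",
            atoms_added=ChemicalFormula({"C": 1, "H": 1, "O": 2}),
            charge=-1,
        ),
    ]


def default_adducts(polarity: str | None = None) -> list[AdductSpec]:
    """The default adduct set, optionally restricted to one polarity."""
    adducts = _default_adduct_set()
    if polarity is None:
        return adducts
    if polarity not in ("positive", "negative"):
        raise ValueError(f"unknown polarity {polarity!r}")
    return [a for a in adducts if a.polarity == polarity]


def load_adducts(path: str | Path) -> list[AdductSpec]:
    """Load adduct definitions from a YAML list.

    Each entry carries ``label``, ``polarity``, ``charge`` and optional
    ``atoms_added`` / ``atoms_removed`` formula strings.
    """
    with open(path, "r", encoding="utf-8") as handle:
        raw = yaml.safe_load(handle)
    if not isinstance(raw, list) or not raw:
        raise ValueError(f"adduct file {path} must contain a non-empty YAML list")
    adducts = []
    for entry in raw:
        adducts.append(
            AdductSpec(
                label=entry["label"],
                polarity=entry["polarity"],
                atoms_added=parse_formula(entry["atoms_added"])
                if entry.get("atoms_added")
                else ChemicalFormula(),
                atoms_removed=parse_formula(entry["atoms_removed"])
                if entry.get("atoms_removed")
                else ChemicalFormula(),
                charge=int(entry["charge"]),
            )
        )
    return adducts


@dataclass(frozen=True, order=True)
class IonCandidate:
    """One (compound, adduct) theoretical ion, sortable by m/z."""

    theoretical_mz: float
    compound_id: str
    adduct_label: str

    def __post_init__(self) -> None:
        if self.theoretical_mz <= 0:
            raise ValueError("theoretical m/z must be positive")


def build_ion_index(
    library: Sequence[CompoundRecord],
    adducts: Sequence[AdductSpec],
    mz_range: tuple[float, float] = (50.0, 1200.0),
) -> list[IonCandidate]:
    """Cross the library with the adduct set and keep ions inside ``mz_range``.

    Returns candidates sorted ascending by theoretical m/z (ties by
    compound_id, then adduct label), ready for binary search.
    """
    if not library:
        raise ValueError("compound library is empty")
    lo, hi = mz_range
    if not lo < hi:
        raise ValueError(f"invalid m/z range {mz_range}")
    seen = set()
    candidates = []
    for record in library:
        if record.compound_id in seen:
            raise ValueError(f"duplicate compound_id {record.compound_id!r}")
        seen.add(record.compound_id)
        for adduct in adducts:
            mz = record.neutral_mass + adduct.mass_shift
            if lo <= mz <= hi:
                candidates.append(IonCandidate(mz, record.compound_id, adduct.label))
    candidates.sort()
    return candidates


def candidates_in_window(
    index: Sequence[IonCandidate], mz: float, tol_ppm: float
) -> list[IonCandidate]:
    """All candidates with |ppm error| <= tol_ppm, via bisection on the index."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    delta = mz * tol_ppm * 1e-6
    mzs = [c.theoretical_mz for c in index]
    lo = bisect.bisect_left(mzs, mz - delta)
    hi = bisect.bisect_right(mzs, mz + delta)
    return [
        c
        for c in index[lo:hi]
        if abs(mz - c.theoretical_mz) / c.theoretical_mz * 1e6 <= tol_ppm
    ]


def load_library(path: str | Path) -> list[CompoundRecord]:
    """Read a compound library CSV.

    Expected header: ``compound_id,name,formula,class,smiles,source`` (the last
    two columns may be empty).
    """
    records = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle)
        required = {"compound_id", "name", "formula", "class"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"library {path} must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for row in reader:
            cid = row["compound_id"].strip()
            if cid in seen:
                raise ValueError(f"duplicate compound_id {cid!r} in {path}")
            seen.add(cid)
            records.append(
                CompoundRecord(
                    compound_id=cid,
                    name=row["name"].strip(),
                    formula=parse_formula(row["formula"].strip()),
                    metabolite_class=row["class"].strip(),
                    smiles=(row.get("smiles") or "").strip() or None,
                    source=(row.get("source") or "").strip() or None,
                )
            )
    if not records:
        raise ValueError(f"library {path} contains no compounds")
    return records


def bundled_library_path() -> Path:
    return Path(str(resources.files("seedmsi").joinpath("data/minilib.csv")))


def bundled_library() -> list[CompoundRecord]:
    """The mini-library of named seed metabolites shipped with the package."""
    return load_library(bundled_library_path())
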