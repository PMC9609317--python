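"""Chemical registry for the pesticide-mixture screen.

Holds the identities of the 20 test pesticides, their known metabolites and
the internal standards, together with the ion-mobility library values
(2-decimal m/z in Da and collision cross section in Å²) for the compounds
detectable by IMS-MS, and the parent→metabolite biotransformation edges.

Monoisotopic masses are computed from elemental composition with IUPAC/CODATA
constants; library m/z values are reproduced through singly charged
electrospray adducts (protonation, deprotonation, sodiation, ammoniation)
with electron-mass-corrected shifts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

__all__ = [
    "ELEMENT_MASSES",
    "ADDUCT_DELTAS",
    "PROTON_MASS",
    "CompoundRecord",
    "ReferenceLibrary",
    "AdductAssignment",
    "LibraryError",
    "monoisotopic_mass",
    "parse_formula",
    "adduct_mz",
    "infer_adduct",
    "load_library",
    "save_library",
]

# IUPAC monoisotopic masses (Da), most-abundant isotope.
ELEMENT_MASSES: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "Na": 22.9897692809,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
}

ELECTRON_MASS = 0.00054857990907
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS  # 1.007276...

# Mass shift (Da) for singly charged adducts, electron-corrected.
ADDUCT_DELTAS: Mapping[str, float] = {
    "M+H": PROTON_MASS,
    "M-H": -PROTON_MASS,
    "M+Na": ELEMENT_MASSES["Na"] - ELECTRON_MASS,
    "M+NH4": ELEMENT_MASSES["N"] + 4 * ELEMENT_MASSES["H"] - ELECTRON_MASS,
}

# Deterministic tie-break order for adduct inference.
_ADDUCT_ORDER = ("M+H", "M-H", "M+Na", "M+NH4")

ROLES = ("parent", "metabolite", "internal_standard")

AMBIGUOUS = "ambiguous"

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class LibraryError(ValueError):
    """Raised for malformed or inconsistent reference libraries."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    >>> parse_formula("C9H11Cl3NO3PS")["Cl"]
    3
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"malformed formula: {formula!r}")
    counts: dict[str, int] = {}
    for element, digits in _FORMULA_TOKEN.findall(formula):
        if not element:
            continue
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    elements = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in elements)


def monoisotopic_mass(formula: Mapping[str, int]) -> float:
    """Monoisotopic mass (Da) of a neutral molecule from element counts."""
    total = 0.0
    for element, count in formula.items():
        if element not in ELEMENT_MASSES:
            raise ValueError(f"unknown element: {element!r}")
        if not isinstance(count, int) or count <= 0:
            raise ValueError(f"element count must be a positive integer: {element}={count!r}")
        total += ELEMENT_MASSES[element] * count
    return total


def adduct_mz(neutral_mass: float, adduct: str) -> float:
    """m/z of a singly charged adduct of a neutral molecule."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    if adduct not in ADDUCT_DELTAS:
        raise ValueError(f"unsupported adduct: {adduct!r} (supported: {list(ADDUCT_DELTAS)})")
    return neutral_mass + ADDUCT_DELTAS[adduct]


@dataclass(frozen=True)
class AdductAssignment:
    """Outcome of matching a library m/z against the supported adducts.

    ``adduct`` is one of the supported adduct labels, or ``"ambiguous"`` when
    no adduct sits within tolerance of the recorded library m/z.  The signed
    residual (theoretical − library) for every candidate is retained either way.
    """

    adduct: str
    residuals: Mapping[str, float]

    @property
    def is_ambiguous(self) -> bool:
        return self.adduct == AMBIGUOUS


@dataclass
class CompoundRecord:
    """One chemical: identity, composition, ionization and library values.

    ``library_mz``/``library_ccs`` are the IMS-MS reference values (present
    only for compounds actually detected); ``parent_names`` lists the parent
    compounds a metabolite can arise from, empty for parents and standards.
    """

    name: str
    casrn: str
    role: str
    formula: dict[str, int]
    logp: Optional[float] = None
    library_mz: Optional[float] = None
    library_ccs: Optional[float] = None
    adduct: Optional[str] = None
    parent_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"{self.name}: invalid role {self.role!r}")
        if self.role == "metabolite" and not self.parent_names:
            raise ValueError(f"{self.name}: metabolite must name at least one parent")
        if self.role != "metabolite" and self.parent_names:
            raise ValueError(f"{self.name}: only metabolites may have parents")
        if self.library_mz is not None and self.library_mz <= 0:
            raise ValueError(f"{self.name}: library m/z must be positive")
        if self.library_ccs is not None and self.library_ccs <= 0:
            raise ValueError(f"{self.name}: library CCS must be positive")
        for element, count in self.formula.items():
            if not isinstance(count, int) or count <= 0:
                raise ValueError(f"{self.name}: bad count for {element}: {count!r}")
        if self.adduct is not None and self.adduct != AMBIGUOUS and self.adduct not in ADDUCT_DELTAS:
            raise ValueError(f"{self.name}: unsupported adduct {self.adduct!r}")

    @property
    def neutral_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def theoretical_mz(self) -> Optional[float]:
        """Theoretical m/z under the assigned adduct, None if unassigned/ambiguous."""
        if self.adduct is None or self.adduct == AMBIGUOUS:
            return None
        return adduct_mz(self.neutral_mass, self.adduct)


def infer_adduct(record: CompoundRecord, tolerance: float = 0.02) -> AdductAssignment:
    """Assign the adduct whose theoretical m/z is nearest the library value.

    Ties are broken by smallest absolute residual, then by the fixed order
    M+H, M-H, M+Na, M+NH4.  When no adduct falls within ``tolerance`` of the
    library m/z, the assignment is "ambiguous" (a value, not an error) with
    the per-adduct residuals attached.
    """
    if record.library_mz is None:
        raise ValueError(f"{record.name}: no library m/z to infer an adduct from")
    mass = record.neutral_mass
    residuals = {a: adduct_mz(mass, a) - record.library_mz for a in _ADDUCT_ORDER}
    best = min(_ADDUCT_ORDER, key=lambda a: (abs(residuals[a]), _ADDUCT_ORDER.index(a)))
    if abs(residuals[best]) > tolerance:
        return AdductAssignment(AMBIGUOUS, residuals)
    return AdductAssignment(best, residuals)


@dataclass
class ReferenceLibrary:
    """Validated collection of compound records with name-based lookup."""

    entries: list[CompoundRecord]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise LibraryError(f"duplicate compound names: {sorted(dupes)}")
        self._by_name = {e.name: e for e in self.entries}
        for entry in self.entries:
            for parent in entry.parent_names:
                target = self._by_name.get(parent)
                if target is None:
                    raise LibraryError(f"{entry.name}: dangling parent reference {parent!r}")
                if target.role != "parent":
                    raise LibraryError(f"{entry.name}: parent {parent!r} is not a parent compound")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> CompoundRecord:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"compound not in library: {name!r}") from None

    def parents_of(self, name: str) -> set[str]:
        return set(self.get(name).parent_names)

    def metabolites_of(self, parent: str) -> set[str]:
        return {e.name for e in self.entries if parent in e.parent_names}

    @property
    def parents(self) -> list[CompoundRecord]:
        return [e for e in self.entries if e.role == "parent"]

    @property
    def metabolites(self) -> list[CompoundRecord]:
        return [e for e in self.entries if e.role == "metabolite"]

    def detectable(self, role: Optional[str] = None) -> list[CompoundRecord]:
        """Entries with IMS-MS library values, optionally filtered by role."""
        out = [e for e in self.entries if e.library_mz is not None and e.library_ccs is not None]
        if role is not None:
            out = [e for e in out if e.role == role]
        return out


_COLUMNS = ("name", "casrn", "role", "formula", "mz", "ccs", "adduct", "parents")


def _packaged_path():
    return resources.files("mixtox").joinpath("data/default_library.tsv")


def load_library(path: Optional[str | Path] = None) -> ReferenceLibrary:
    """Load a reference library from a tab-separated file.

    With no argument, loads the packaged default (Table of 35 analytes with
    the 12 detectable parents and 8 detectable metabolites) and additionally
    verifies those detectability counts.
    """
    packaged = path is None
    if packaged:
        text = _packaged_path().read_text(encoding="utf-8")
        source = "packaged default"
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise LibraryError(f"{source}: empty library file")
    header = lines[0].rstrip("\n").split("\t")
    if header[: len(_COLUMNS)] != list(_COLUMNS):
        raise LibraryError(f"{source}: expected header {list(_COLUMNS)}, got {header}")
    entries = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        fields += [""] * (len(_COLUMNS) - len(fields))
        row = dict(zip(_COLUMNS, fields))
        try:
            entries.append(
                CompoundRecord(
                    name=row["name"].strip(),
                    casrn=row["casrn"].strip(),
                    role=row["role"].strip(),
                    formula=parse_formula(row["formula"].strip()),
                    library_mz=float(row["mz"]) if row["mz"].strip() else None,
                    library_ccs=float(row["ccs"]) if row["ccs"].strip() else None,
                    adduct=row["adduct"].strip() or None,
                    parent_names=[p.strip() for p in row["parents"].split(";") if p.strip()],
                )
            )
        except ValueError as exc:
            raise LibraryError(f"{source}, row {lineno}: {exc}") from exc
    try:
        library = ReferenceLibrary(entries)
    except LibraryError as exc:
        raise LibraryError(f"{source}: {exc}") from exc
    if packaged:
        n_parent = len(library.detectable("parent"))
        n_metab = len(library.detectable("metabolite"))
        if (n_parent, n_metab) != (12, 8):
            raise LibraryError(
                f"packaged library must have 12 detectable parents and 8 detectable "
                f"metabolites, found {n_parent}/{n_metab}"
            )
    return library


def save_library(library: ReferenceLibrary, path: str | Path) -> None:
    """Write a library in the same tab-separated format ``load_library`` reads."""
    rows = ["\t".join(_COLUMNS)]
    for e in library.entries:
        rows.append(
            "\t".join(
                [
                    e.name,
                    e.casrn,
                    e.role,
                    format_formula(e.formula),
                    repr(e.library_mz) if e.library_mz is not None else "",
                    repr(e.library_ccs) if e.library_ccs is not None else "",
                    e.adduct or "",
                    ";".join(e.parent_names),
                ]
            ).rstrip("\t")
        )
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
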