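"""Chemical-library handling and dose arithmetic.

Parses molecular formulas in Hill notation, computes molar masses from
IUPAC standard atomic weights, converts between molar and mass
concentrations (the unit bridge between screen doses in uM and the
ug/ml figures used when comparing with biomonitoring data), and loads
the screening library table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "ChemicalRecord",
    "parse_formula",
    "hill_formula",
    "molecular_weight",
    "micromolar_to_ug_per_ml",
    "ug_per_ml_to_micromolar",
    "load_library",
    "ATOMIC_WEIGHTS",
]

#: IUPAC 2021 conventional atomic weights, 5 significant figures (g/mol).
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "Be": 9.0122, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "K": 39.098, "Ar": 39.948, "Ca": 40.078,
    "Cr": 51.996, "Mn": 54.938, "Fe": 55.845, "Co": 58.933, "Ni": 58.693,
    "Cu": 63.546, "Zn": 65.38, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Mo": 95.95, "Cd": 112.41, "Sn": 118.71, "Sb": 121.76, "I": 126.90,
    "Ba": 137.33, "W": 183.84, "Pt": 195.08, "Au": 196.97, "Hg": 200.59,
    "Pb": 207.2, "Bi": 208.98,
}

CATEGORIES = frozenset(
    {"pesticide", "phthalate", "crude-oil", "hydraulic-fracturing",
     "dioxin", "plasticizer", "vehicle"}
)

SOLVENTS = frozenset({"DMSO", "water"})

#: Default stock concentration in DMSO (mol/L).
DMSO_STOCK_M = 0.1

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed or chemically invalid formula strings."""


@dataclass(frozen=True)
class ChemicalRecord:
    """One library entry: identity, class, formula and screen dose."""

    name: str
    category: str
    formula: str
    molar_mass: float  # g/mol
    screen_dose: float  # umol/L
    solvent: str = "DMSO"
    stock_conc: float = DMSO_STOCK_M  # mol/L

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.solvent not in SOLVENTS:
            raise ValueError(f"unknown solvent {self.solvent!r}")
        if self.screen_dose < 0:
            raise ValueError("screen_dose must be >= 0")
        if self.formula and self.molar_mass <= 0:
            raise ValueError("molar_mass must be > 0 for a non-empty formula")

    @property
    def screen_dose_ug_per_ml(self) -> float:
        return micromolar_to_ug_per_ml(self.screen_dose, self.molar_mass)


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    Only plain element-count formulas are accepted (no isotopes,
    charges, hydrates or parentheses); every chemical in the screening
    library fits this grammar.

    >>> parse_formula("C16H22O4")
    {'C': 16, 'H': 22, 'O': 4}
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(
                f"malformed token at position {pos} in {formula!r}")
        elem, digits = m.group(1), m.group(2)
        if elem not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {elem!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"count for {elem} must be positive")
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    if pos != len(formula):
        raise FormulaError(f"trailing garbage in {formula!r}")
    return counts


def hill_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill string: C first, H second, others alphabetical.

    Without carbon all elements (including H) sort alphabetically.
    """
    def fmt(el: str) -> str:
        n = counts[el]
        return el if n == 1 else f"{el}{n}"

    elems = sorted(counts)
    if "C" in counts:
        ordered = ["C"] + (["H"] if "H" in counts else [])
        ordered += [e for e in elems if e not in ("C", "H")]
    else:
        ordered = elems
    return "".join(fmt(e) for e in ordered)


def molecular_weight(counts: Mapping[str, int]) -> float:
    """Molar mass (g/mol) as the count-weighted sum of atomic weights."""
    try:
        return sum(n * ATOMIC_WEIGHTS[el] for el, n in counts.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"no standard atomic weight for {exc.args[0]!r}")


def micromolar_to_ug_per_ml(conc_um: float, molar_mass: float) -> float:
    """Convert a molar concentration (umol/L) to a mass one (ug/ml).

    1 umol/L of a compound with molar mass M g/mol weighs M ug per
    litre, i.e. M/1000 ug/ml.
    """
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    return conc_um * molar_mass / 1000.0


def ug_per_ml_to_micromolar(conc_ug_ml: float, molar_mass: float) -> float:
    """Inverse of :func:`micromolar_to_ug_per_ml`."""
    if conc_ug_ml < 0:
        raise ValueError("concentration must be >= 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    return conc_ug_ml * 1000.0 / molar_mass


REQUIRED_COLUMNS = ["name", "category", "formula", "dose_uM", "solvent"]


def load_library(path: str | Path) -> list[ChemicalRecord]:
    """Load and validate a chemical-library CSV.

    The table must carry exactly the header
    ``name,category,formula,dose_uM,solvent``.  Doses are in umol/L;
    the screen default is 100 uM with reduced doses representable per
    row (e.g. 10 uM for the ten-fold diluted set, 1 uM for
    chlorpyrifos-methyl, 0.1 uM for TCDD).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    if df.empty:
        raise ValueError("empty chemical library table")
    dupes = df["name"][df["name"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate chemical name(s): {', '.join(dupes)}")
    records = []
    for row in df.itertuples(index=False):
        dose = float(row.dose_uM)
        if dose < 0:
            raise ValueError(f"negative dose for {row.name!r}")
        counts = parse_formula(str(row.formula))
        records.append(
            ChemicalRecord(
                name=str(row.name),
                category=str(row.category),
                formula=hill_formula(counts),
                molar_mass=molecular_weight(counts),
                screen_dose=dose,
                solvent=str(row.solvent),
            )
        )
    return records
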