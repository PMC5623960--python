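"""Elemental masses, formula arithmetic and adduct bookkeeping.

All masses are monoisotopic, in daltons, from the IUPAC atomic-mass
evaluation. Formula strings use Hill-ish notation without charges,
e.g. ``"C27H42O"`` or ``"C55H98O6"``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

# IUPAC 2021 monoisotopic atomic masses (Da)
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "Mg": 23.985041697,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885268,
    "K": 38.9637064864,
    "Ca": 39.962590863,
}

ELECTRON_MASS = 0.000548579909
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS  # 1.00727646...

#: mass difference between 13C and 12C; spacing of isotopologue peaks at z=1
C13_C12_DELTA = 1.0033548378

#: natural abundance of 13C relative to 12C, per carbon atom
C13_ABUNDANCE = 0.011

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into an element -> count map."""
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        pos = match.end()
        element, number = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(number) if number else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def formula_to_string(counts: dict[str, int]) -> str:
    order = ["C", "H"] + sorted(e for e in counts if e not in ("C", "H"))
    parts = []
    for element in order:
        n = counts.get(element, 0)
        if n <= 0:
            continue
        parts.append(element if n == 1 else f"{element}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


def isotope_envelope(formula: str | dict[str, int], n_isotopologues: int = 3) -> list[float]:
    """Relative abundances of M, M+1, ... truncated at ``n_isotopologues``.

    Carbon-dominated two/three-isotopologue approximation: each of the
    ``nC`` carbons contributes 1.1% chance of being 13C; heavier elements
    are ignored (negligible at the lipid mass range modeled here).
    """
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    n_c = counts.get("C", 0)
    p = C13_ABUNDANCE
    env = [1.0]
    if n_isotopologues > 1:
        env.append(n_c * p)
    if n_isotopologues > 2:
        env.append(n_c * (n_c - 1) / 2.0 * p * p)
    return env[:n_isotopologues]


# --- adducts ------------------------------------------------------------

#: neutral monoisotopic masses of the attached moieties of the four common
#: positive-mode adduct components
ADDUCT_COMPONENT_MASS: dict[str, float] = {
    "H": MONOISOTOPIC_MASS["H"],
    "NH4": MONOISOTOPIC_MASS["N"] + 4 * MONOISOTOPIC_MASS["H"],
    "Na": MONOISOTOPIC_MASS["Na"],
    "K": MONOISOTOPIC_MASS["K"],
}

ADDUCT_COMPONENTS = ("H", "NH4", "Na", "K")


@dataclass(frozen=True)
class Adduct:
    """A positive-mode adduct, e.g. [M+H]+ or [M+H+Na]2+."""

    components: tuple[str, ...]
    duplicate_mass: bool = field(default=False, compare=False)

    @property
    def charge(self) -> int:
        return len(self.components)

    @property
    def label(self) -> str:
        inner = "".join(f"+{c}" for c in self.components)
        z = self.charge
        return f"[M{inner}]{z if z > 1 else ''}+"

    @property
    def mass_shift(self) -> float:
        """Summed neutral component mass minus the removed electrons."""
        total = sum(ADDUCT_COMPONENT_MASS[c] for c in self.components)
        return total - self.charge * ELECTRON_MASS

    def mz_from_neutral(self, neutral_mass: float) -> float:
        return (neutral_mass + self.mass_shift) / self.charge

    def neutral_from_mz(self, mz: float) -> float:
        return mz * self.charge - self.mass_shift


def get_adduct(label: str) -> Adduct:
    """Resolve a label like ``"[M+Na]+"`` or ``"[M+H+K]2+"``."""
    m = re.fullmatch(r"\[M((?:\+(?:H|NH4|Na|K))+)\](\d?)\+", label)
    if not m:
        raise ValueError(f"unrecognized adduct label {label!r}")
    components = tuple(m.group(1).lstrip("+").split("+"))
    adduct = Adduct(components)
    stated = int(m.group(2)) if m.group(2) else 1
    if stated != adduct.charge:
        raise ValueError(f"charge mismatch in adduct label {label!r}")
    return adduct
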