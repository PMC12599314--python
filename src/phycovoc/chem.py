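"""Elemental formulas, monoisotopic masses and PTR-MS mass conventions.

PTR-MS soft ionization by H3O+ yields the protonated ion M+H+; every peak is
therefore labeled by the neutral monoisotopic mass plus the proton mass.
Formulas are plain element-count mappings restricted to C, H, N, O, S — the
elements relevant for the natural-abundance isotopologue bookkeeping.
"""

from __future__ import annotations

import re

__all__ = [
    "MONOISOTOPIC",
    "PROTON_MASS",
    "M1_OFFSET",
    "M2_OFFSET",
    "parse_formula",
    "formula_mass",
    "formula_to_string",
    "protonated_mass",
]

#: Monoisotopic masses (Da) of the light isotopes.
MONOISOTOPIC = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

#: Mass added by protonation (M + H+), following the instrument convention.
PROTON_MASS = 1.008

#: Mass offset of a single-heavy-isotope M+1 satellite (13C or 15N).
M1_OFFSET = 1.003
#: Mass offset of a single-heavy-isotope M+2 satellite (18O or 34S).
M2_OFFSET = 2.004

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula string like ``"C6H6"`` into element counts.

    Only C, H, N, O, S are accepted; anything else raises ``ValueError``.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC:
            raise ValueError(f"unsupported element {elem!r} in {formula!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: dict[str, int] | str) -> float:
    """Monoisotopic neutral mass (Da) of a formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return sum(MONOISOTOPIC[el] * n for el, n in formula.items())


def formula_to_string(formula: dict[str, int]) -> str:
    """Render element counts as a Hill-ordered formula string."""
    order = ["C", "H", "N", "O", "S"]
    parts = []
    for el in order:
        n = formula.get(el, 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    return "".join(parts)


def protonated_mass(neutral_mass: float) -> float:
    """Observed m/z of the protonated ion for a neutral of given mass."""
    return neutral_mass + PROTON_MASS
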