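"""Molecular-formula strings and element counts.

Peaks in formula-assigned FT-MS data carry either a molecular formula string
(e.g. ``"C6H12O6"``) or explicit element counts for C, H, N, O, S and P.  This
module converts between the two representations.  Parsing follows Hill-style
``element + optional count`` tokens (an absent count means 1); by default the
element alphabet is restricted to the six elements the data model tracks, with
a strict flag controlling whether anything else is rejected or ignored.
"""

from __future__ import annotations

import re

# Fixed symbol order used throughout: formula writing, elemental-composition
# class labels, and the column order of count tables.
ELEMENTS: tuple[str, ...] = ("C", "H", "N", "O", "S", "P")

# Monoisotopic masses (Da) for computing neutral masses of generated formulas.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


def parse_formula(formula: str, strict: bool = True) -> dict[str, int]:
    """Parse a molecular formula string into C,H,N,O,S,P counts.

    Parameters
    ----------
    formula:
        Hill-style formula, e.g. ``"C6H12O6"`` or ``"C5H9NO4S"``.
    strict:
        If True (default), any element outside {C,H,N,O,S,P} raises
        :class:`FormulaError`; if False, unknown elements are ignored.

    Returns
    -------
    dict mapping each of the six tracked symbols to a non-negative count.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError(f"empty or non-string formula: {formula!r}")
    counts = dict.fromkeys(ELEMENTS, 0)
    pos = 0
    text = formula.strip()
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        symbol, digits = m.group(1), m.group(2)
        n = int(digits) if digits else 1
        if symbol in counts:
            counts[symbol] += n
        elif strict:
            raise FormulaError(
                f"element {symbol!r} in formula {formula!r} is outside C,H,N,O,S,P"
            )
        pos = m.end()
    return counts


def format_formula(counts: dict[str, int]) -> str:
    """Render element counts as a formula string in fixed C,H,N,O,S,P order."""
    parts = []
    for el in ELEMENTS:
        n = int(counts.get(el, 0) or 0)
        if n == 1:
            parts.append(el)
        elif n > 1:
            parts.append(f"{el}{n}")
    if not parts:
        raise FormulaError("all element counts are zero")
    return "".join(parts)


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Neutral monoisotopic mass (Da) from element counts."""
    return sum(MONOISOTOPIC_MASS[el] * int(counts.get(el, 0) or 0) for el in ELEMENTS)
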