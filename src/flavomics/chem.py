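"""Exact molecular-formula arithmetic.

Parsing of molecular formula strings, monoisotopic (most-abundant-isotope)
mass computation, adduct/cation m/z and ppm mass-error calculation.  All
other modules build on the primitives defined here.

Masses are IUPAC/CODATA monoisotopic atomic masses, kept to at least six
decimal places.  ``[M+H]+`` ions add the mass of a *proton* (not a hydrogen
atom); permanently charged (native cation) species subtract one electron
mass per charge.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "ElementCounts",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_error",
    "round_half_up",
]

#: Monoisotopic masses of the most abundant isotope, in Da.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}

PROTON_MASS = 1.007276466621  #: Da, mass of H+
ELECTRON_MASS = 0.000548579909  #: Da

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_CHARS = {"+": +1, "-": -1, "−": -1, "–": -1}


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid element arithmetic."""


@dataclass(frozen=True)
class ElementCounts:
    """A parsed molecular formula: element counts plus a net charge.

    Counts are element-symbol -> non-negative integer; ``charge`` is the
    net number of elementary charges (``+1`` for a native flavylium cation,
    ``0`` for a neutral molecule).

    Instances are immutable and support element-wise ``+`` and ``-``;
    subtraction that would drive any count negative raises
    :class:`FormulaError`.
    """

    counts: tuple[tuple[str, int], ...] = field(default=())
    charge: int = 0

    @classmethod
    def from_dict(cls, counts: dict[str, int], charge: int = 0) -> "ElementCounts":
        for el, n in counts.items():
            if el not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
        items = tuple(sorted((el, n) for el, n in counts.items() if n > 0))
        return cls(items, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __add__(self, other: "ElementCounts") -> "ElementCounts":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) + n
        return ElementCounts.from_dict(merged, self.charge + other.charge)

    def __sub__(self, other: "ElementCounts") -> "ElementCounts":
        merged = self.as_dict()
        for el, n in other.counts:
            merged[el] = merged.get(el, 0) - n
            if merged[el] < 0:
                raise FormulaError(
                    f"subtraction yields negative count for element {el}"
                )
        return ElementCounts.from_dict(merged, self.charge - other.charge)

    def __bool__(self) -> bool:
        return bool(self.counts)


def parse_formula(text: str) -> ElementCounts:
    """Parse a molecular formula string such as ``"C29H32O18"``.

    Trailing ``+``/``-`` characters encode the net charge, one elementary
    charge per sign character (``"C22H23O11+"`` has charge ``+1``).

    Raises
    ------
    FormulaError
        If the string is empty, contains an unknown element symbol, or
        does not match the element-count grammar.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    stripped = text.strip()
    if not stripped:
        raise FormulaError("empty formula string")

    charge = 0
    while stripped and stripped[-1] in _CHARGE_CHARS:
        charge += _CHARGE_CHARS[stripped[-1]]
        stripped = stripped[:-1]
    if not stripped:
        raise FormulaError(f"formula {text!r} has no element symbols")

    counts: dict[str, int] = {}
    pos = 0
    while pos < len(stripped):
        m = _TOKEN.match(stripped, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, digits = m.group(1), m.group(2)
        if el not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return ElementCounts.from_dict(counts, charge)


def format_formula(f: ElementCounts) -> str:
    """Encode counts and charge back to a string (Hill order: C, H, rest)."""
    d = f.as_dict()
    parts: list[str] = []
    for el in ("C", "H"):
        if el in d:
            n = d.pop(el)
            parts.append(el if n == 1 else f"{el}{n}")
    for el in sorted(d):
        n = d[el]
        parts.append(el if n == 1 else f"{el}{n}")
    sign = "+" * f.charge if f.charge > 0 else "-" * (-f.charge)
    return "".join(parts) + sign


def monoisotopic_mass(f: ElementCounts) -> float:
    """Neutral-atom monoisotopic mass in Da (charge is ignored here).

    The sum over elements of count x most-abundant-isotope mass.  Charge
    correction (electron mass) is applied by :func:`adduct_mz`, not here.
    """
    return sum(n * ATOMIC_MASS[el] for el, n in f.counts)


def adduct_mz(m: float, adduct: str = "[M+H]+", z: int = 1) -> float:
    """m/z of an ion formed from a neutral of monoisotopic mass ``m``.

    Supported adduct kinds:

    ``"[M+H]+"``
        Protonation: ``(m + z * proton) / z``.
    ``"M+"``
        Native cation (e.g. anthocyanidin flavylium): the species is
        already charged, so ``(m - z * electron) / z`` where ``m`` is the
        neutral-atom sum of the cation's formula.
    """
    if z < 1:
        raise ValueError(f"charge z must be >= 1, got {z}")
    if adduct == "[M+H]+":
        return (m + z * PROTON_MASS) / z
    if adduct == "M+":
        return (m - z * ELECTRON_MASS) / z
    raise ValueError(f"unsupported adduct kind: {adduct!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    ``1e6 * (observed - theoretical) / theoretical``; raises
    :class:`ValueError` when ``theoretical`` is not strictly positive.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical mass must be > 0, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round-half-up to ``ndigits`` decimals (for comparison with printed
    table values; full precision is kept everywhere internally)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def mz_within(observed: float, theoretical: float, tol_ppm: float) -> bool:
    """True when |ppm error| <= tolerance."""
    return abs(ppm_error(observed, theoretical)) <= tol_ppm


def mda_error(observed: float, theoretical: float) -> float:
    """Absolute-scale mass error in millidaltons, signed."""
    return 1e3 * (observed - theoretical)


def is_close_mda(observed: float, theoretical: float, tol_mda: float) -> bool:
    return math.fabs(mda_error(observed, theoretical)) <= tol_mda
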