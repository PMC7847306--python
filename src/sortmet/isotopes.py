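"""Elemental formulas, monoisotopic masses and isotopologue envelopes.

Isotope patterns are predicted from a fixed embedded table of natural
isotopic abundances (IUPAC 2021 representative values) so that results
do not depend on an external database version.  The M+k relative
abundance of a formula is the convolution, over all atoms, of each
element's single-atom distribution across nominal mass shifts,
normalised to the monoisotopic (all-lightest-isotope) peak.
"""

from __future__ import annotations

import re

import numpy as np

from .config import FormatError, ValidationError

PROTON_MASS = 1.007276466

# monoisotopic atomic masses (Da) of the supported elements
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "K": 38.96370668,
}

# per-element natural abundance by nominal mass shift relative to the
# lightest isotope: index 0 = monoisotopic, index k = M+k
ISOTOPE_SHIFT_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Cl": (0.7576, 0.0, 0.2424),
    "Na": (1.0,),
    "K": (0.932581, 0.000117, 0.067302),
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-order elemental formula like ``C6H12O6``.

    Returns an element -> count mapping; the empty string parses to an
    empty composition.  Unknown element symbols raise :class:`FormatError`.
    """
    composition: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormatError(
                f"cannot parse formula {formula!r} at position {pos}"
            )
        pos = match.end()
        element, count = match.group(1), match.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormatError(
                f"unknown element {element!r} in formula {formula!r} "
                f"(supported: {sorted(MONOISOTOPIC_MASS)})"
            )
        n = int(count) if count else 1
        if n < 1:
            raise FormatError(f"zero count for {element!r} in {formula!r}")
        composition[element] = composition.get(element, 0) + n
    if pos != len(formula):
        raise FormatError(f"cannot parse formula {formula!r} at position {pos}")
    return composition


def monoisotopic_mass(formula: str) -> float:
    """Neutral monoisotopic mass of a formula in Da."""
    composition = parse_formula(formula)
    if not composition:
        raise ValidationError("empty formula has no mass")
    return float(
        sum(MONOISOTOPIC_MASS[el] * n for el, n in composition.items())
    )


def adduct_mz(formula: str, adduct: str) -> float:
    """Theoretical m/z of a formula under a protonation adduct.

    ``[M+H]+`` adds and ``[M-H]-`` subtracts one proton (1.007276 Da);
    the electron mass is accounted for by using the proton rather than
    the hydrogen-atom mass.
    """
    mass = monoisotopic_mass(formula)
    if adduct == "[M+H]+":
        return mass + PROTON_MASS
    if adduct == "[M-H]-":
        return mass - PROTON_MASS
    raise ValidationError(f"unsupported adduct {adduct!r}")


def _power_convolve(dist: np.ndarray, n: int, length: int) -> np.ndarray:
    """First ``length`` coefficients of ``dist`` convolved with itself n times.

    Truncation is exact for the leading coefficients: entry k of a
    convolution depends only on entries 0..k of the factors.
    """
    result = np.zeros(length)
    result[0] = 1.0
    base = np.zeros(length)
    base[: min(length, dist.size)] = dist[:length]
    while n:
        if n & 1:
            result = np.convolve(result, base)[:length]
        base = np.convolve(base, base)[:length]
        n >>= 1
    return result


def isotope_pattern(formula: str, max_shift: int = 2) -> np.ndarray:
    """Relative abundances of the M..M+max_shift isotopologue peaks.

    The per-element abundance vectors over nominal mass shifts are raised
    to the atom count by repeated convolution and multiplied across
    elements; the result is normalised so the monoisotopic peak M is 1.
    The empty formula yields ``[1, 0, ..., 0]``.
    """
    if max_shift < 0:
        raise ValidationError("max_shift must be >= 0")
    composition = parse_formula(formula)
    length = max_shift + 1
    pattern = np.zeros(length)
    pattern[0] = 1.0
    for element, count in composition.items():
        dist = np.asarray(ISOTOPE_SHIFT_ABUNDANCE[element], dtype=float)
        pattern = np.convolve(pattern, _power_convolve(dist, count, length))[
            :length
        ]
    if pattern[0] <= 0:
        raise ValidationError(f"degenerate isotope pattern for {formula!r}")
    return pattern / pattern[0]
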