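"""Molecular formulas, atomic weights and elemental weight fractions.

The unit of analysis throughout the package is a small organic compound
given as a flat element-count formula (e.g. ``C30H44N6O2``) plus an
optional mass density.  The elemental weight fractions W_i computed here
feed the photon mixture rule

    (mu/rho)_mixture = sum_i W_i * (mu/rho)_i

so their normalisation (sum W_i == 1) is load-bearing and is enforced to
1e-12.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional

__all__ = [
    "ATOMIC_WEIGHTS",
    "ATOMIC_NUMBERS",
    "FormulaError",
    "parse_formula",
    "hill_formula",
    "molecular_weight",
    "weight_fractions",
    "ElementComposition",
    "CompoundSpec",
]

#: IUPAC standard atomic weights (conventional values, g/mol).  A fixed
#: table is shipped rather than taken from an external source so results
#: are bit-identical across environments.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Cu": 63.546,
    "Zn": 65.38,
    "Br": 79.904,
    "I": 126.904,
}

ATOMIC_NUMBERS: dict[str, int] = {
    "H": 1, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Na": 11, "Mg": 12,
    "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17, "K": 19, "Ca": 20,
    "Fe": 26, "Cu": 29, "Zn": 30, "Br": 35, "I": 53,
}


class FormulaError(ValueError):
    """Raised for unparsable or chemically unknown formula text."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a flat element-count formula into ``{symbol: count}``.

    The grammar is repeated ``(ElementSymbol, optional count)`` groups
    with an implicit count of 1 — no parentheses, hydrates, charges or
    isotopes.  Repeated symbols accumulate.

    Raises
    ------
    FormulaError
        For empty input, unrecognised element symbols, zero counts or
        stray characters; the message names the offending token.
    """
    if not isinstance(formula, str) or not formula.strip():
        raise FormulaError("empty formula")
    text = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"unparsable token at position {pos}: {text[pos:pos + 3]!r}"
            )
        symbol, digits = m.group(1), m.group(2)
        if symbol not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r} in {formula!r}")
        counts[symbol] = counts.get(symbol, 0) + n
        pos = m.end()
    return counts


def hill_formula(counts: Mapping[str, int]) -> str:
    """Canonical Hill-order string: C first, then H, then alphabetical.

    Without carbon, all symbols are alphabetical.  Count 1 is implicit.
    """
    if not counts:
        raise FormulaError("empty composition")
    symbols = list(counts)
    if "C" in counts:
        rest = sorted(s for s in symbols if s not in ("C", "H"))
        order = ["C"] + (["H"] if "H" in counts else []) + rest
    else:
        order = sorted(symbols)
    return "".join(
        f"{s}{counts[s]}" if counts[s] != 1 else s for s in order
    )


def molecular_weight(
    counts: Mapping[str, int],
    atomic_weights: Optional[Mapping[str, float]] = None,
) -> float:
    """Molecular weight in g/mol: sum of count x standard atomic weight."""
    weights = ATOMIC_WEIGHTS if atomic_weights is None else atomic_weights
    total = 0.0
    for symbol, n in counts.items():
        if symbol not in weights:
            raise FormulaError(f"no atomic weight for element {symbol!r}")
        if n <= 0:
            raise FormulaError(f"non-positive count for {symbol!r}")
        total += n * weights[symbol]
    if total <= 0:
        raise FormulaError("empty composition")
    return total


def weight_fractions(
    counts: Mapping[str, int],
    atomic_weights: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Elemental mass fractions W_i = count_i * A_i / MW; sums to 1."""
    weights = ATOMIC_WEIGHTS if atomic_weights is None else atomic_weights
    mw = molecular_weight(counts, weights)
    return {s: n * weights[s] / mw for s, n in counts.items()}


@dataclass(frozen=True)
class ElementComposition:
    """Integer element counts with derived mass fractions and weight."""

    counts: Mapping[str, int]
    weight_fractions: Mapping[str, float]
    molecular_weight: float

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        atomic_weights: Optional[Mapping[str, float]] = None,
    ) -> "ElementComposition":
        mw = molecular_weight(counts, atomic_weights)
        wf = weight_fractions(counts, atomic_weights)
        return cls(counts=dict(counts), weight_fractions=wf, molecular_weight=mw)

    @classmethod
    def from_formula(
        cls,
        formula: str,
        atomic_weights: Optional[Mapping[str, float]] = None,
    ) -> "ElementComposition":
        return cls.from_counts(parse_formula(formula), atomic_weights)

    def hill(self) -> str:
        return hill_formula(self.counts)


@dataclass(frozen=True)
class CompoundSpec:
    """A compound identifier, formula and optional mass density (g/cm^3)."""

    identifier: str
    formula: str
    density: Optional[float] = None
    _composition: ElementComposition = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.density is not None and not self.density > 0:
            raise ValueError(
                f"density must be positive, got {self.density!r} for "
                f"{self.identifier!r}"
            )
        object.__setattr__(
            self, "_composition", ElementComposition.from_formula(self.formula)
        )

    @property
    def composition(self) -> ElementComposition:
        return self._composition

    def with_density(self, density: float) -> "CompoundSpec":
        return CompoundSpec(self.identifier, self.formula, density)
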