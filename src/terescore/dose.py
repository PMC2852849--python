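"""Aglycone-equivalent dose conversion.

Plant isoflavones occur mostly as glucoside conjugates (genistin,
daidzin, glycitin) and their 6''-O-malonyl / 6''-O-acetyl esters, while
binding affinities and trial dosing conventions are stated for the
sugar-free aglycones.  Scoring therefore runs entirely in
aglycone-equivalent milligrams: a conjugate intake is rescaled by the
molar-mass ratio parent/conjugate (mg-to-mg, the field's
"aglycone equivalents" convention), which for any true conjugate is a
factor strictly between 0 and 1.

Molar masses are computed from Hill-notation molecular formulas rather
than tabulated, so the formula is the single source of truth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .affinity import canonical_name
from .errors import FormulaParseError, UnregisteredCompoundError

__all__ = [
    "Compound",
    "molar_mass",
    "default_registry",
    "aglycone_equivalent",
    "conversion_factor",
]

# IUPAC standard atomic weights, 4-decimal conventional values.
_ATOMIC_MASS = {
    "H": 1.0080,
    "B": 10.8100,
    "C": 12.0110,
    "N": 14.0070,
    "O": 15.9990,
    "F": 18.9984,
    "Na": 22.9898,
    "Mg": 24.3050,
    "P": 30.9738,
    "S": 32.0600,
    "Cl": 35.4500,
    "K": 39.0983,
    "Ca": 40.0780,
    "Fe": 55.8450,
    "Zn": 65.3800,
    "Se": 78.9710,
    "Br": 79.9040,
    "I": 126.9045,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def molar_mass(molecular_formula: str) -> float:
    """Molar mass in g/mol of a Hill-notation formula such as ``"C15H10O5"``.

    Raises :class:`FormulaParseError` for unknown element symbols,
    zero counts, or anything that is not a plain element/count string.
    """
    formula = molecular_formula.strip()
    if not formula:
        raise FormulaParseError("empty molecular formula")
    pos = 0
    total = 0.0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            break
        symbol, count_str = match.groups()
        if symbol not in _ATOMIC_MASS:
            raise FormulaParseError(
                f"unknown element symbol {symbol!r} in formula {molecular_formula!r}"
            )
        count = int(count_str) if count_str else 1
        if count <= 0:
            raise FormulaParseError(
                f"element {symbol!r} has non-positive count in {molecular_formula!r}"
            )
        total += _ATOMIC_MASS[symbol] * count
        pos = match.end()
    if pos != len(formula):
        raise FormulaParseError(
            f"malformed molecular formula {molecular_formula!r} at position {pos}"
        )
    return total


@dataclass(frozen=True)
class Compound:
    """A chemical form: an aglycone, or a conjugate pointing at its parent aglycone."""

    name: str
    molecular_formula: str
    parent_aglycone: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", canonical_name(self.name))
        if self.parent_aglycone is not None:
            object.__setattr__(
                self, "parent_aglycone", canonical_name(self.parent_aglycone)
            )
        molar_mass(self.molecular_formula)  # validate eagerly

    @property
    def is_aglycone(self) -> bool:
        return self.parent_aglycone is None


def _build_registry(compounds: Iterable[Compound]) -> dict[str, Compound]:
    registry = {c.name: c for c in compounds}
    for c in registry.values():
        if c.parent_aglycone is not None:
            parent = registry.get(c.parent_aglycone)
            if parent is None or not parent.is_aglycone:
                raise ValueError(
                    f"{c.name!r}: parent aglycone {c.parent_aglycone!r} "
                    "is not a registered aglycone"
                )
    return registry


def default_registry() -> dict[str, Compound]:
    """The packaged compound registry.

    Five aglycones, their three 7-O-glucosides, and the 6''-O-malonyl
    (adds C3H2O3) and 6''-O-acetyl (adds C2H2O) esters of each
    glucoside — the forms that dominate soy and red-clover extracts.
    """
    return _build_registry(
        [
            Compound("genistein", "C15H10O5"),
            Compound("daidzein", "C15H10O4"),
            Compound("glycitein", "C16H12O5"),
            Compound("formononetin", "C16H12O4"),
            Compound("biochanin a", "C16H12O5"),
            Compound("estradiol", "C18H24O2"),
            Compound("genistin", "C21H20O10", "genistein"),
            Compound("daidzin", "C21H20O9", "daidzein"),
            Compound("glycitin", "C22H22O10", "glycitein"),
            Compound("malonylgenistin", "C24H22O13", "genistein"),
            Compound("malonyldaidzin", "C24H22O12", "daidzein"),
            Compound("malonylglycitin", "C25H24O13", "glycitein"),
            Compound("acetylgenistin", "C23H22O11", "genistein"),
            Compound("acetyldaidzin", "C23H22O10", "daidzein"),
            Compound("acetylglycitin", "C24H24O11", "glycitein"),
        ]
    )


def _lookup(compound: str | Compound, registry: Mapping[str, Compound]) -> Compound:
    if isinstance(compound, Compound):
        return compound
    key = canonical_name(compound)
    try:
        return registry[key]
    except KeyError:
        raise UnregisteredCompoundError(compound, list(registry)) from None


def conversion_factor(
    compound: str | Compound, registry: Mapping[str, Compound] | None = None
) -> float:
    """Mass ratio m(parent aglycone) / m(conjugate); 1.0 for an aglycone."""
    registry = default_registry() if registry is None else registry
    comp = _lookup(compound, registry)
    if comp.is_aglycone:
        return 1.0
    parent = _lookup(comp.parent_aglycone, registry)
    return molar_mass(parent.molecular_formula) / molar_mass(comp.molecular_formula)


def aglycone_equivalent(
    intake_mg: float,
    compound: str | Compound,
    registry: Mapping[str, Compound] | None = None,
) -> tuple[str, float]:
    """Convert an intake of any registered form to (aglycone name, mg aglycone/day).

    An aglycone passes through unchanged; a conjugate is rescaled by
    the parent/conjugate molar-mass ratio.
    """
    if intake_mg < 0:
        raise ValueError(f"intake must be >= 0 mg/day, got {intake_mg}")
    registry = default_registry() if registry is None else registry
    comp = _lookup(compound, registry)
    if comp.is_aglycone:
        return comp.name, intake_mg
    return comp.parent_aglycone, intake_mg * conversion_factor(comp, registry)
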