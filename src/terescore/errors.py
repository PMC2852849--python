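"""Exception hierarchy.

Every error a caller can meaningfully handle derives from
:class:`TereError`, so the CLI can convert any validation problem
into a clean exit-1 diagnostic without pattern-matching messages.
"""

from __future__ import annotations


class TereError(Exception):
    """Base class for all validation and input errors raised by terescore."""


class UnknownCompoundError(TereError):
    """A formulation references a compound with no affinity data.

    Carries the query name and the list of known compounds so the
    message can tell the user what *is* available.
    """

    def __init__(self, compound_name: str, known: list[str]):
        self.compound_name = compound_name
        self.known = sorted(known)
        super().__init__(
            f"no affinity data for compound {compound_name!r}; "
            f"known compounds: {', '.join(self.known)}"
        )


class UnregisteredCompoundError(TereError):
    """A formulation names a chemical form absent from the compound registry."""

    def __init__(self, compound_name: str, known: list[str]):
        self.compound_name = compound_name
        self.known = sorted(known)
        super().__init__(
            f"compound {compound_name!r} is not in the registry; "
            f"registered forms: {', '.join(self.known)}"
        )


class FormulaParseError(TereError):
    """A molecular formula could not be parsed into element counts."""


class AffinityValidationError(TereError):
    """An affinity table violates an invariant (negative RBA, dangling proxy, ...)."""


class FormulationSchemaError(TereError):
    """A formulation file violates the expected schema.

    ``row`` is the 1-based data-row number when the problem is row-local.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class DegenerateFormulationError(TereError):
    """Risk/benefit partition requested for a formulation with zero total binding."""
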