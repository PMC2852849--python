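"""Reading and writing formulation files.

The interchange format is a UTF-8 CSV with header columns
``formulation_label, compound, intake_mg, is_aglycone_equivalent`` and
an optional ``annotation`` column.  One file carries any number of
formulations; rows sharing a label form one formulation, and duplicate
compounds within a formulation are merged by summing intakes at load
time.  Decimal separators are periods only — locale-dependent parsing
is rejected for reproducibility.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormulationSchemaError
from .scoring import Formulation, FormulationComponent

__all__ = ["read_formulations", "write_formulations", "FORMULATION_COLUMNS"]

FORMULATION_COLUMNS = ("formulation_label", "compound", "intake_mg", "is_aglycone_equivalent")
_OPTIONAL_COLUMNS = ("annotation",)

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(text: str, row: int) -> bool:
    value = text.strip().lower()
    if value in _TRUE:
        return True
    if value in _FALSE:
        return False
    raise FormulationSchemaError(
        f"is_aglycone_equivalent must be true/false, got {text!r}", row=row
    )


def _parse_intake(text: str, row: int) -> float:
    try:
        intake = float(text)
    except ValueError:
        raise FormulationSchemaError(f"intake_mg {text!r} is not a decimal number", row=row)
    if intake < 0:
        raise FormulationSchemaError(f"intake_mg must be >= 0, got {text}", row=row)
    return intake


def read_formulations(path: str | Path) -> list[Formulation]:
    """Read all formulations from a CSV file, in first-appearance order.

    Raises :class:`FormulationSchemaError` with the offending row
    number for unknown/missing columns, non-decimal or negative
    intakes, and for an empty file.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise FormulationSchemaError(f"{path}: empty file")
        fields = [f.strip() for f in reader.fieldnames]
        missing = [c for c in FORMULATION_COLUMNS[:3] if c not in fields]
        if missing:
            raise FormulationSchemaError(f"{path}: missing columns {missing}")
        unknown = [
            f for f in fields if f not in FORMULATION_COLUMNS + _OPTIONAL_COLUMNS
        ]
        if unknown:
            raise FormulationSchemaError(f"{path}: unknown columns {unknown}")

        order: list[str] = []
        components: dict[str, list[FormulationComponent]] = {}
        annotations: dict[str, str | None] = {}
        for row_num, row in enumerate(reader, start=1):
            label = (row.get("formulation_label") or "").strip()
            compound = (row.get("compound") or "").strip()
            if not label or not compound:
                raise FormulationSchemaError(
                    "formulation_label and compound must be non-empty", row=row_num
                )
            intake = _parse_intake((row.get("intake_mg") or "").strip(), row_num)
            flag_text = (row.get("is_aglycone_equivalent") or "").strip()
            flag = _parse_bool(flag_text, row_num) if flag_text else True
            if label not in components:
                order.append(label)
                components[label] = []
                annotations[label] = None
            annotation = (row.get("annotation") or "").strip()
            if annotation:
                annotations[label] = annotation
            components[label].append(
                FormulationComponent(compound, intake, is_aglycone_equivalent=flag)
            )
        if not order:
            raise FormulationSchemaError(f"{path}: no formulation rows")

    return [
        Formulation(label, _merge(components[label]), annotations[label])
        for label in order
    ]


def _merge(components: Iterable[FormulationComponent]) -> tuple[FormulationComponent, ...]:
    """Merge duplicate (compound, conversion-flag) entries by summing intakes."""
    merged: dict[tuple[str, bool], float] = {}
    for comp in components:
        key = (comp.compound_name, comp.is_aglycone_equivalent)
        merged[key] = merged.get(key, 0.0) + comp.intake_mg
    return tuple(
        FormulationComponent(name, mg, is_aglycone_equivalent=flag)
        for (name, flag), mg in merged.items()
    )


def _format_number(value: float) -> str:
    text = f"{value:.10f}".rstrip("0").rstrip(".")
    return text if text else "0"


def write_formulations(formulations: Sequence[Formulation], path: str | Path) -> None:
    """Write formulations to the CSV interchange format (round-trips with read)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(FORMULATION_COLUMNS + _OPTIONAL_COLUMNS)
        for form in formulations:
            for comp in form.components:
                writer.writerow(
                    [
                        form.label,
                        comp.compound_name,
                        _format_number(comp.intake_mg),
                        "true" if comp.is_aglycone_equivalent else "false",
                        form.annotation or "",
                    ]
                )
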