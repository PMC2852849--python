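"""Multi-formulation comparison reports.

Scores a batch of formulations against one affinity table and lays the
results out as one row per formulation — label, outcome annotation,
component summary, TE, TERE fraction, absolute alpha load, risk
percentage and the relevance flag — ranked by descending TE (larger TE
reads as closer to estradiol's reference activity).  Rendering targets
are a stable TSV (the machine interface), an aligned plain-text table,
and a YAML document.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from typing import Sequence

import yaml

from .affinity import AffinityTable, default_affinity_table
from .errors import TereError
from .scoring import (
    Formulation,
    Mode,
    Relevance,
    ScoreBreakdown,
    score_formulation,
)

__all__ = [
    "ComparisonRow",
    "ComparisonReport",
    "compare_formulations",
    "render_report",
    "REPORT_COLUMNS",
]

REPORT_COLUMNS = (
    "label",
    "annotation",
    "components",
    "TE",
    "TERE",
    "alpha_load",
    "risk_percent",
    "relevance",
)


def _sig(value: float, digits: int) -> str:
    """Render to *digits* significant figures without scientific notation."""
    if value == 0:
        return "0"
    if math.isinf(value):
        return "inf"
    from decimal import Decimal

    exponent = math.floor(math.log10(abs(value)))
    quantum = Decimal(1).scaleb(exponent - digits + 1)
    text = format(Decimal(repr(value)).quantize(quantum), "f")
    if "." in text:
        text = text.rstrip("0").rstrip(".")
    return text


def _component_summary(breakdown: ScoreBreakdown) -> str:
    return " + ".join(
        f"{_sig(c.intake_mg, 6)} mg {c.compound_name}" for c in breakdown.per_compound
    )


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    annotation: str
    components: str
    te: float
    tere_fraction: str
    tere_denominator: float
    alpha_load: float
    risk_percent: float | None
    relevance: Relevance

    def cells(self) -> tuple[str, ...]:
        risk = "" if self.risk_percent is None else f"{self.risk_percent:.1f}%"
        return (
            self.label,
            self.annotation,
            self.components,
            _sig(self.te, 6),
            self.tere_fraction,
            _sig(self.alpha_load, 3),
            risk,
            self.relevance.value,
        )


@dataclass(frozen=True)
class ComparisonReport:
    affinity_label: str
    mode: Mode
    rows: tuple[ComparisonRow, ...]


def compare_formulations(
    formulations: Sequence[Formulation],
    table: AffinityTable | None = None,
    mode: Mode | str = Mode.COMBINED,
    sort: bool = True,
) -> ComparisonReport:
    """Score each formulation and assemble a comparison report.

    Rows are ordered by descending TE, ties broken by label ascending;
    ``sort=False`` preserves the input order instead (useful to mirror
    a published table laid out by citation).  Scoring errors are
    re-raised annotated with the offending formulation's label.
    """
    if not formulations:
        raise TereError("compare_formulations needs at least one formulation")
    table = default_affinity_table() if table is None else table
    mode = Mode(mode)
    rows = []
    for form in formulations:
        try:
            bd = score_formulation(form, table, mode)
        except TereError as exc:
            raise TereError(f"formulation {form.label!r}: {exc}") from exc
        rows.append(
            ComparisonRow(
                label=bd.formulation_label,
                annotation=bd.annotation or "",
                components=_component_summary(bd),
                te=bd.te,
                tere_fraction=bd.tere_fraction,
                tere_denominator=bd.tere_denominator,
                alpha_load=bd.alpha_load,
                risk_percent=bd.risk_percent,
                relevance=bd.relevance,
            )
        )
    if sort:
        rows.sort(key=lambda r: (-r.te, r.label))
    return ComparisonReport(affinity_label=table.label, mode=mode, rows=tuple(rows))


def _render_tsv(report: ComparisonReport) -> str:
    out = ["\t".join(REPORT_COLUMNS)]
    out += ["\t".join(row.cells()) for row in report.rows]
    return "\n".join(out) + "\n"


def _render_text(report: ComparisonReport) -> str:
    header = REPORT_COLUMNS
    table = [header] + [row.cells() for row in report.rows]
    widths = [max(len(r[i]) for r in table) for i in range(len(header))]
    buf = io.StringIO()
    buf.write(f"# affinity set: {report.affinity_label}   mode: {report.mode.value}\n")
    for i, r in enumerate(table):
        buf.write("  ".join(cell.ljust(w) for cell, w in zip(r, widths)).rstrip() + "\n")
        if i == 0:
            buf.write("  ".join("-" * w for w in widths) + "\n")
    return buf.getvalue()


def _render_structured(report: ComparisonReport) -> str:
    doc = {
        "affinity_label": report.affinity_label,
        "mode": report.mode.value,
        "rows": [
            {
                "label": r.label,
                "annotation": r.annotation,
                "components": r.components,
                "te": r.te,
                "tere": r.tere_fraction,
                "tere_denominator": None
                if math.isinf(r.tere_denominator)
                else r.tere_denominator,
                "alpha_load": r.alpha_load,
                "risk_percent": r.risk_percent,
                "relevance": r.relevance.value,
            }
            for r in report.rows
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


_RENDERERS = {"tsv": _render_tsv, "text": _render_text, "structured": _render_structured}


def render_report(report: ComparisonReport, fmt: str = "text") -> str:
    """Render a report as ``tsv``, aligned ``text``, or ``structured`` YAML."""
    try:
        renderer = _RENDERERS[fmt]
    except KeyError:
        raise TereError(f"unknown report format {fmt!r}; choose from {sorted(_RENDERERS)}")
    return renderer(report)
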