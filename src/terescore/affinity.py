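"""Relative-binding-affinity (RBA) tables for the two estrogen-receptor subtypes.

An RBA expresses a compound's binding to ER-alpha or ER-beta as a
percentage of estradiol's binding (estradiol = 100).  Values are stored
on that printed percentage scale — 0.860 means 0.860 % — and are only
divided by 100 inside the scoring step, so the stored numbers stay
identical to the published source table.

The default table ships the Fokialakis et al. competitive-binding data
for estradiol and the four assayed isoflavone aglycones, plus a proxy
rule mapping glycitein onto daidzein's affinities (glycitein was never
assayed; its gut metabolites and low typical intake make daidzein a
conventional stand-in).
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

from .errors import AffinityValidationError, UnknownCompoundError

__all__ = [
    "AffinityRecord",
    "AffinityTable",
    "canonical_name",
    "default_affinity_table",
    "resolve_affinity",
    "load_affinity_table",
    "dump_affinity_table",
]

#: Estradiol's definitional RBA against either receptor subtype.
ESTRADIOL_REFERENCE = 100.0


def canonical_name(name: str) -> str:
    """Canonicalize a compound name: lowercase, hyphens to spaces, collapsed whitespace.

    ``"Biochanin-A"`` and ``"biochanin  A"`` both canonicalize to
    ``"biochanin a"`` — the literature uses both spellings.
    """
    return re.sub(r"\s+", " ", name.replace("-", " ")).strip().lower()


@dataclass(frozen=True)
class AffinityRecord:
    """Per-compound RBA pair (percent of estradiol) for the two ER subtypes."""

    compound_name: str
    rba_alpha: float
    rba_beta: float
    source: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_name", canonical_name(self.compound_name))
        if self.rba_alpha < 0 or self.rba_beta < 0:
            raise AffinityValidationError(
                f"{self.compound_name!r}: RBA values must be >= 0, "
                f"got alpha={self.rba_alpha}, beta={self.rba_beta}"
            )


@dataclass(frozen=True)
class AffinityTable:
    """A named set of affinity records with one-hop proxy resolution.

    ``proxies`` maps a compound with no assayed affinity onto the
    compound whose affinities stand in for it.  Proxy chains are
    forbidden: every proxy target must be a direct record.
    """

    records: Mapping[str, AffinityRecord]
    proxies: Mapping[str, str] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        records = {canonical_name(k): v for k, v in self.records.items()}
        proxies = {
            canonical_name(k): canonical_name(v) for k, v in self.proxies.items()
        }
        for alias, target in proxies.items():
            if target not in records:
                raise AffinityValidationError(
                    f"proxy {alias!r} -> {target!r}: target has no affinity record"
                )
            if alias in records:
                raise AffinityValidationError(
                    f"proxy {alias!r} shadows a direct record"
                )
        object.__setattr__(self, "records", records)
        object.__setattr__(self, "proxies", proxies)

    def known_compounds(self) -> list[str]:
        return sorted(set(self.records) | set(self.proxies))

    def resolve(self, compound_name: str) -> AffinityRecord:
        """Return the affinity record for *compound_name*, following one proxy hop.

        Matching is case-insensitive and whitespace/hyphen-insensitive.
        A proxied record is re-labeled with the query compound's name so
        downstream reports show the compound actually in the formulation.

        Raises
        ------
        UnknownCompoundError
            If neither a record nor a proxy exists for the name.
        """
        key = canonical_name(compound_name)
        if not key:
            raise UnknownCompoundError(compound_name, self.known_compounds())
        if key in self.records:
            return self.records[key]
        if key in self.proxies:
            target = self.records[self.proxies[key]]
            return replace(target, compound_name=key)
        raise UnknownCompoundError(compound_name, self.known_compounds())


def default_affinity_table() -> AffinityTable:
    """The packaged affinity table (Fokialakis et al. competitive-binding RBAs).

    Estradiol's ER-beta binding is reported in the source as "<= 100";
    it is stored here as exactly 100 so that the estradiol reference
    score is well defined.
    """
    src = "Fokialakis et al. ER binding assay"
    records = [
        AffinityRecord("estradiol", 100.0, 100.0, src),
        AffinityRecord("daidzein", 0.031, 0.020, src),
        AffinityRecord("genistein", 0.860, 43.9, src),
        AffinityRecord("formononetin", 0.084, 0.017, src),
        AffinityRecord("biochanin a", 0.094, 0.010, src),
    ]
    return AffinityTable(
        records={r.compound_name: r for r in records},
        proxies={"glycitein": "daidzein"},
        label="fokialakis-default",
    )


def resolve_affinity(table: AffinityTable, compound_name: str) -> AffinityRecord:
    """Functional alias for :meth:`AffinityTable.resolve`."""
    return table.resolve(compound_name)


def _table_from_mapping(doc: dict) -> AffinityTable:
    if not isinstance(doc, dict):
        raise AffinityValidationError("affinity document must be a mapping")
    raw_records = doc.get("records")
    if not isinstance(raw_records, list) or not raw_records:
        raise AffinityValidationError("affinity document needs a non-empty 'records' list")
    records: dict[str, AffinityRecord] = {}
    for i, item in enumerate(raw_records, start=1):
        if not isinstance(item, dict) or "name" not in item:
            raise AffinityValidationError(f"record {i}: expected mapping with a 'name' field")
        try:
            rec = AffinityRecord(
                compound_name=str(item["name"]),
                rba_alpha=float(item["rba_alpha"]),
                rba_beta=float(item["rba_beta"]),
                source=str(item.get("source", "")),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise AffinityValidationError(f"record {i} ({item.get('name')!r}): {exc}") from exc
        records[rec.compound_name] = rec
    proxies = doc.get("proxies") or {}
    if not isinstance(proxies, dict):
        raise AffinityValidationError("'proxies' must be a mapping of name -> name")
    return AffinityTable(
        records=records,
        proxies={str(k): str(v) for k, v in proxies.items()},
        label=str(doc.get("label", "")),
    )


def _table_from_csv(text: str) -> AffinityTable:
    reader = csv.reader(io.StringIO(text))
    rows = [r for r in reader if r and any(cell.strip() for cell in r)]
    if not rows:
        raise AffinityValidationError("empty affinity CSV")
    start = 0
    if rows[0] and canonical_name(rows[0][0]) in {"name", "compound", "compound name"}:
        start = 1
    records: dict[str, AffinityRecord] = {}
    for i, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 3:
            raise AffinityValidationError(f"line {i}: expected name, rba_alpha, rba_beta")
        try:
            rec = AffinityRecord(row[0], float(row[1]), float(row[2]))
        except ValueError as exc:
            raise AffinityValidationError(f"line {i}: {exc}") from exc
        records[rec.compound_name] = rec
    return AffinityTable(records=records, label="csv")


def load_affinity_table(source: str | Path) -> AffinityTable:
    """Load an affinity table from a YAML document or a 3-column CSV.

    *source* is a path, or a string containing the document itself.
    The YAML form carries ``label``, ``records`` (list of
    ``{name, rba_alpha, rba_beta, source?}``) and optional ``proxies``;
    the CSV form is ``name,rba_alpha,rba_beta`` with no proxies.
    Negative affinities and dangling proxies are rejected.
    """
    if isinstance(source, Path) or (
        "\n" not in str(source) and Path(str(source)).exists()
    ):
        path = Path(source)
        text = path.read_text(encoding="utf-8")
        is_csv = path.suffix.lower() == ".csv"
    else:
        text = str(source)
        is_csv = False
    if not is_csv:
        try:
            doc = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise AffinityValidationError(f"cannot parse affinity document: {exc}") from exc
        if isinstance(doc, dict):
            return _table_from_mapping(doc)
        # not a mapping: fall through and try CSV
    return _table_from_csv(text)


def dump_affinity_table(table: AffinityTable) -> str:
    """Serialize a table to the YAML document form accepted by :func:`load_affinity_table`."""
    doc = {
        "label": table.label,
        "records": [
            {
                "name": r.compound_name,
                "rba_alpha": r.rba_alpha,
                "rba_beta": r.rba_beta,
                **({"source": r.source} if r.source else {}),
            }
            for r in sorted(table.records.values(), key=lambda r: r.compound_name)
        ],
        "proxies": dict(sorted(table.proxies.items())),
    }
    return yaml.safe_dump(doc, sort_keys=False)
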