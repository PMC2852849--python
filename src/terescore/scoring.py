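"""Core TE/TERE scoring.

The model is an equivalency-factor-style additive potency score.  For a
formulation with daily intakes :math:`d_i` (mg/day, aglycone
equivalents) and relative binding affinities :math:`RBA^{\\alpha}_i`,
:math:`RBA^{\\beta}_i` (percent of estradiol), the per-receptor bound
contribution of compound *i* is

    c_i^r = d_i * RBA_i^r / 100          (theoretical units, r in {alpha, beta})

The Theoretical Efficacy is the additive total,
``TE = sum(c^alpha) + sum(c^beta)`` in the default *combined* mode, or
``sum(c^beta)`` alone in *beta_only* mode.  TERE expresses TE against
the estradiol reference of 100: the fraction 1/x with
``x = 100 / TE``.  Alpha-channel binding is the risk channel (tumour
proliferation concern), beta-channel binding the benefit channel
(bone / cardiovascular / CNS); the partition is reported both as
percentages of TE and as the absolute alpha load.

Additivity is the model's central assumption: the score is meaningless
where compounds act synergistically or antagonistically.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .affinity import AffinityTable, canonical_name, default_affinity_table
from .dose import Compound, aglycone_equivalent, default_registry
from .errors import DegenerateFormulationError, TereError

__all__ = [
    "Mode",
    "Relevance",
    "FormulationComponent",
    "Formulation",
    "CompoundContribution",
    "ScoreBreakdown",
    "receptor_contribution",
    "score_formulation",
    "classify_relevance",
    "risk_benefit",
    "DEFAULT_RELEVANCE_THRESHOLD",
]

#: TERE denominator above which expected bioactivity is negligible.  The
#: anchor is the minimal effective genistein dose, 15 mg/day on the beta
#: channel, whose denominator is 15.2 (conventionally rounded to "1/15"):
#: 1/22.8 (10 mg) showed no relevant bioactivity, 1/15.2 did, so the
#: boundary case itself classifies as potentially relevant and anything
#: weaker classifies LOW.
DEFAULT_RELEVANCE_THRESHOLD = 15.2


class Mode(str, enum.Enum):
    """Which receptor channels enter TE."""

    COMBINED = "combined"
    BETA_ONLY = "beta_only"


class Relevance(str, enum.Enum):
    """Bioactivity-relevance classification from the TERE threshold."""

    LOW = "LOW"
    POTENTIALLY_RELEVANT = "POTENTIALLY_RELEVANT"


@dataclass(frozen=True)
class FormulationComponent:
    """One (compound, daily intake) entry of a formulation.

    ``is_aglycone_equivalent=True`` (the default) means the intake is
    already expressed in aglycone milligrams and no conversion applies.
    """

    compound_name: str
    intake_mg: float
    is_aglycone_equivalent: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "compound_name", canonical_name(self.compound_name))
        if self.intake_mg < 0:
            raise TereError(
                f"{self.compound_name!r}: intake must be >= 0 mg/day, got {self.intake_mg}"
            )


@dataclass(frozen=True)
class Formulation:
    """A labeled set of components, optionally annotated with an observed outcome."""

    label: str
    components: tuple[FormulationComponent, ...]
    annotation: str | None = None

    def __post_init__(self) -> None:
        components = tuple(self.components)
        if not components:
            raise TereError(f"formulation {self.label!r} has no components")
        if not any(c.intake_mg > 0 for c in components):
            raise TereError(
                f"formulation {self.label!r} needs at least one component with intake > 0"
            )
        object.__setattr__(self, "components", components)

    def scaled(self, factor: float) -> "Formulation":
        """The same formulation with every intake multiplied by *factor* > 0."""
        return Formulation(
            self.label,
            tuple(
                FormulationComponent(
                    c.compound_name, c.intake_mg * factor, c.is_aglycone_equivalent
                )
                for c in self.components
            ),
            self.annotation,
        )


@dataclass(frozen=True)
class CompoundContribution:
    """Per-compound receptor-bound contributions (theoretical units, no dimension)."""

    compound_name: str
    intake_mg: float
    alpha_contribution: float
    beta_contribution: float


@dataclass(frozen=True)
class ScoreBreakdown:
    """Full scoring result for one formulation."""

    formulation_label: str
    mode: Mode
    per_compound: tuple[CompoundContribution, ...]
    alpha_total: float
    beta_total: float
    te: float
    tere_denominator: float  # inf when te == 0
    risk_percent: float | None  # None when alpha_total + beta_total == 0
    benefit_percent: float | None
    annotation: str | None = None

    @property
    def alpha_load(self) -> float:
        """Absolute alpha-channel total — the risk-side load, not a percentage."""
        return self.alpha_total

    @property
    def tere(self) -> float:
        """TERE as a decimal fraction of the estradiol reference (te / 100)."""
        return self.te / 100.0

    @property
    def tere_fraction(self) -> str:
        """TERE rendered as the conventional '1/x' string, x to 2 decimals."""
        if math.isinf(self.tere_denominator):
            return "1/inf"
        return f"1/{self.tere_denominator:.2f}"

    @property
    def relevance(self) -> Relevance:
        return classify_relevance(self.tere_denominator)


def receptor_contribution(intake_mg: float, rba: float) -> float:
    """Bound contribution of one compound at one receptor: intake_mg * rba / 100."""
    if intake_mg < 0:
        raise TereError(f"intake must be >= 0, got {intake_mg}")
    if rba < 0:
        raise TereError(f"RBA must be >= 0, got {rba}")
    return intake_mg * rba / 100.0


def _to_aglycone_components(
    formulation: Formulation, registry: Mapping[str, Compound]
) -> dict[str, float]:
    """Convert + merge components into {aglycone-equivalent name: total mg}."""
    intakes: dict[str, list[float]] = {}
    for comp in formulation.components:
        if comp.is_aglycone_equivalent:
            name, mg = comp.compound_name, comp.intake_mg
        else:
            name, mg = aglycone_equivalent(comp.intake_mg, comp.compound_name, registry)
        intakes.setdefault(name, []).append(mg)
    # fsum + sorted order: totals are bit-identical regardless of how the
    # input components are ordered or split
    return {name: math.fsum(mgs) for name, mgs in sorted(intakes.items())}


def score_formulation(
    formulation: Formulation,
    table: AffinityTable | None = None,
    mode: Mode | str = Mode.COMBINED,
    registry: Mapping[str, Compound] | None = None,
) -> ScoreBreakdown:
    """Score one formulation against an affinity table.

    Components not flagged as aglycone equivalents are first converted
    to aglycone milligrams; entries resolving to the same compound are
    merged by intake summation.  The TERE denominator is computed from
    the *unrounded* TE.  A formulation whose every affinity is zero
    scores te = 0 with an infinite denominator and an undefined
    risk/benefit partition (``None``), rather than raising.
    """
    table = default_affinity_table() if table is None else table
    registry = default_registry() if registry is None else registry
    mode = Mode(mode)

    rows: list[CompoundContribution] = []
    for name, mg in _to_aglycone_components(formulation, registry).items():
        record = table.resolve(name)
        rows.append(
            CompoundContribution(
                compound_name=name,
                intake_mg=mg,
                alpha_contribution=receptor_contribution(mg, record.rba_alpha),
                beta_contribution=receptor_contribution(mg, record.rba_beta),
            )
        )

    alpha_total = sum(r.alpha_contribution for r in rows)
    beta_total = sum(r.beta_contribution for r in rows)
    te = beta_total if mode is Mode.BETA_ONLY else alpha_total + beta_total
    denominator = 100.0 / te if te > 0 else math.inf
    grand = alpha_total + beta_total
    if grand > 0:
        risk = 100.0 * alpha_total / grand
        benefit = 100.0 * beta_total / grand
    else:
        risk = benefit = None

    return ScoreBreakdown(
        formulation_label=formulation.label,
        mode=mode,
        per_compound=tuple(rows),
        alpha_total=alpha_total,
        beta_total=beta_total,
        te=te,
        tere_denominator=denominator,
        risk_percent=risk,
        benefit_percent=benefit,
        annotation=formulation.annotation,
    )


def classify_relevance(
    tere_denominator: float,
    threshold_denominator: float = DEFAULT_RELEVANCE_THRESHOLD,
) -> Relevance:
    """Classify expected bioactivity from the TERE denominator.

    A denominator strictly above the threshold predicts negligible
    bioactivity.  The default threshold, 15.2, is the denominator of the
    minimal genistein dose observed to reduce hot flushes (15 mg/day,
    beta channel) — conventionally quoted as "1/15" — so the boundary
    case itself classifies as potentially relevant.
    """
    if tere_denominator <= 0:
        raise TereError(f"TERE denominator must be > 0, got {tere_denominator}")
    if tere_denominator > threshold_denominator:
        return Relevance.LOW
    return Relevance.POTENTIALLY_RELEVANT


def risk_benefit(breakdown: ScoreBreakdown) -> tuple[float, float]:
    """(risk %, benefit %) partition of total binding across alpha/beta channels.

    Raises :class:`DegenerateFormulationError` when both channel totals
    are zero and the partition is undefined.
    """
    if breakdown.risk_percent is None or breakdown.benefit_percent is None:
        raise DegenerateFormulationError(
            f"formulation {breakdown.formulation_label!r} has zero total binding; "
            "risk/benefit partition undefined"
        )
    return breakdown.risk_percent, breakdown.benefit_percent
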