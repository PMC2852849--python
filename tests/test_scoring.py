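"""Core TE/TERE scoring: worked examples, modes, edge cases."""

import math

import pytest

from terescore import (
    DegenerateFormulationError,
    Formulation,
    FormulationComponent,
    Mode,
    Relevance,
    TereError,
    UnknownCompoundError,
    classify_relevance,
    receptor_contribution,
    risk_benefit,
    score_formulation,
)
from terescore.scoring import CompoundContribution, ScoreBreakdown

from conftest import make_formulation


@pytest.mark.parametrize(
    "intake, rba, expected",
    [
        (75, 43.9, 32.925),   # genistein beta channel at 75 mg/day
        (45, 0.860, 0.387),   # genistein alpha channel at 45 mg/day
        (0, 43.9, 0.0),
        (25, 0.0, 0.0),
    ],
)
def test_receptor_contribution(intake, rba, expected):
    assert receptor_contribution(intake, rba) == pytest.approx(expected, abs=1e-12)


def test_receptor_contribution_rejects_negative_inputs():
    with pytest.raises(TereError):
        receptor_contribution(-1, 10)
    with pytest.raises(TereError):
        receptor_contribution(1, -10)


def test_two_mix_demonstration_assay_1(assay1, table):
    """25 mg daidzein + 75 mg genistein: TE ~ 33.5, TERE ~ 1/3, risk 1.9 %."""
    bd = score_formulation(assay1, table)
    assert bd.te == pytest.approx(33.58275, abs=1e-9)
    assert bd.tere_denominator == pytest.approx(2.98, abs=0.01)
    assert bd.risk_percent == pytest.approx(1.9, abs=0.05)
    assert bd.benefit_percent == pytest.approx(98.1, abs=0.05)
    assert bd.alpha_load == pytest.approx(0.653, abs=0.001)
    assert bd.tere_fraction == "1/2.98"


def test_two_mix_demonstration_assay_2(assay2, table):
    """The inverted 75/25 mix: TE ~ 11.2, TERE ~ 1/8.9, risk 2.1 %."""
    bd = score_formulation(assay2, table)
    assert bd.te == pytest.approx(11.22825, abs=1e-9)
    assert bd.tere_denominator == pytest.approx(8.91, abs=0.02)
    assert bd.risk_percent == pytest.approx(2.1, abs=0.05)
    assert bd.benefit_percent == pytest.approx(97.9, abs=0.05)
    assert bd.alpha_load == pytest.approx(0.238, abs=0.001)


def test_estradiol_reference_scores_fifty(table):
    """1 mg estradiol binds both channels at 100 %: te = 2, denominator 50."""
    bd = score_formulation(make_formulation("e2", ("estradiol", 1)), table)
    assert bd.te == pytest.approx(2.0)
    assert bd.tere_denominator == pytest.approx(50.0)
    assert risk_benefit(bd) == (pytest.approx(50.0), pytest.approx(50.0))


@pytest.mark.parametrize(
    "mg, denominator, relevance",
    [(10, 22.8, Relevance.LOW), (15, 15.2, Relevance.POTENTIALLY_RELEVANT)],
)
def test_beta_only_genistein_dose_threshold_cases(table, mg, denominator, relevance):
    """Single-compound genistein doses scored on the beta channel alone."""
    bd = score_formulation(make_formulation("g", ("genistein", mg)), table, mode="beta_only")
    assert bd.mode is Mode.BETA_ONLY
    assert bd.te == pytest.approx(mg * 43.9 / 100, abs=1e-12)
    assert bd.tere_denominator == pytest.approx(denominator, rel=0.002)
    assert bd.relevance is relevance


def test_beta_only_te_drops_alpha_but_partition_keeps_both_channels(assay1, table):
    combined = score_formulation(assay1, table, mode="combined")
    beta = score_formulation(assay1, table, mode="beta_only")
    assert beta.te == pytest.approx(combined.beta_total)
    assert beta.risk_percent == pytest.approx(combined.risk_percent)
    assert beta.alpha_load == combined.alpha_load


@pytest.mark.parametrize(
    "denominator, expected",
    [
        (22.8, Relevance.LOW),
        (15.2, Relevance.POTENTIALLY_RELEVANT),  # boundary = minimal relevant dose
        (15.21, Relevance.LOW),
        (math.inf, Relevance.LOW),
        (1.0, Relevance.POTENTIALLY_RELEVANT),
    ],
)
def test_classify_relevance(denominator, expected):
    assert classify_relevance(denominator) is expected


def test_classify_relevance_custom_threshold_and_bad_input():
    assert classify_relevance(9.0, threshold_denominator=10) is Relevance.POTENTIALLY_RELEVANT
    with pytest.raises(TereError):
        classify_relevance(0.0)


def test_risk_benefit_partition_sums_to_100(table):
    bd = score_formulation(
        make_formulation("m", ("genistein", 13.7), ("formononetin", 2.2)), table
    )
    risk, benefit = risk_benefit(bd)
    assert risk + benefit == pytest.approx(100.0, abs=1e-9)


def test_all_alpha_formulation_partitions_100_0():
    breakdown = ScoreBreakdown(
        formulation_label="x",
        mode=Mode.COMBINED,
        per_compound=(CompoundContribution("x", 1.0, 0.5, 0.0),),
        alpha_total=0.5,
        beta_total=0.0,
        te=0.5,
        tere_denominator=200.0,
        risk_percent=100.0,
        benefit_percent=0.0,
    )
    assert risk_benefit(breakdown) == (100.0, 0.0)


def test_zero_affinity_formulation_is_degenerate_not_an_exception():
    from terescore import AffinityRecord, AffinityTable

    table = AffinityTable(records={"inertol": AffinityRecord("inertol", 0.0, 0.0)})
    bd = score_formulation(make_formulation("z", ("inertol", 10)), table)
    assert bd.te == 0.0
    assert math.isinf(bd.tere_denominator)
    assert bd.risk_percent is None
    assert bd.relevance is Relevance.LOW
    with pytest.raises(DegenerateFormulationError):
        risk_benefit(bd)


def test_unknown_compound_propagates(table):
    with pytest.raises(UnknownCompoundError, match="quercetin"):
        score_formulation(make_formulation("q", ("quercetin", 10)), table)


def test_conjugate_components_convert_before_scoring(table):
    """100 mg genistin (flagged unconverted) scores like ~62.5 mg genistein."""
    form = Formulation(
        "conj",
        (FormulationComponent("genistin", 100, is_aglycone_equivalent=False),),
    )
    bd = score_formulation(form, table)
    direct = score_formulation(make_formulation("agl", ("genistein", 62.500433645326694)), table)
    assert bd.te == pytest.approx(direct.te, rel=1e-9)
    assert bd.per_compound[0].compound_name == "genistein"


def test_duplicate_components_merge(table):
    split = make_formulation("s", ("genistein", 40), ("genistein", 5))
    whole = make_formulation("s", ("genistein", 45))
    a, b = score_formulation(split, table), score_formulation(whole, table)
    assert a.te == pytest.approx(b.te, rel=1e-15)
    assert len(a.per_compound) == 1


def test_empty_and_all_zero_formulations_rejected():
    with pytest.raises(TereError):
        Formulation("empty", ())
    with pytest.raises(TereError):
        make_formulation("zero", ("genistein", 0))


def test_tere_decimal_and_fraction_are_synchronized(assay1, table):
    bd = score_formulation(assay1, table)
    assert bd.tere == pytest.approx(bd.te / 100)
    assert bd.tere_fraction == f"1/{bd.tere_denominator:.2f}"
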