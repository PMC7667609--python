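"""Patient-level screening, cohort assembly, 2x2 metrics and the
strategy-comparison report."""

from __future__ import annotations

import itertools
import math

import pytest

from dicscreen import (
    ConfusionCounts,
    Strategy,
    TermLexicon,
    assemble_cohort,
    compare_strategies,
    confusion,
    default_strategies,
    disagreement_report,
    screen_patient,
    sensitivity_specificity,
)
from dicscreen.cohort_eval import PatientPrediction

from conftest import make_record

AFFIRM = "Overt DIC with ongoing bleeding."
NEUTRAL = "Patient remains stable on current support."


def _pred(pid, positive, strategy="s"):
    return PatientPrediction(
        patient_id=pid,
        strategy=strategy,
        positive=positive,
        evidence_note_ids=("n",) if positive else (),
    )


# --- screen_patient --------------------------------------------------------


def test_positive_note_inside_stay_notes_only():
    record = make_record(note_texts=[AFFIRM], note_offsets_h=[4])
    pred = screen_patient(record, Strategy(name="notes_only"))
    assert pred.positive and pred.evidence_note_ids == ("P1-N0",)


def test_note_before_admission_is_ignored():
    record = make_record(note_texts=[AFFIRM], note_offsets_h=[-4])
    pred = screen_patient(record, Strategy(name="notes_only"))
    assert not pred.positive and pred.evidence_note_ids == ()


@pytest.mark.parametrize("note_pos", [False, True])
@pytest.mark.parametrize("code_pos", [False, True])
@pytest.mark.parametrize("combine", ["or", "and"])
def test_combined_strategy_truth_table(note_pos, code_pos, combine):
    record = make_record(
        note_texts=[AFFIRM if note_pos else NEUTRAL],
        codes=[("ICD10CM", "D65", 5)] if code_pos else [],
    )
    pred = screen_patient(record, Strategy(name="notes_or_codes", combine=combine))
    expected = (note_pos or code_pos) if combine == "or" else (note_pos and code_pos)
    assert pred.positive is expected
    if pred.positive and code_pos:
        assert pred.evidence_codes


def test_codes_only_ignores_notes():
    record = make_record(note_texts=[AFFIRM])
    assert not screen_patient(record, Strategy(name="codes_only")).positive


def test_screen_requires_a_stay():
    from dicscreen.corpus_model import PatientRecord

    with pytest.raises(ValueError):
        screen_patient(PatientRecord("P0"), Strategy(name="notes_only"))


# --- assemble_cohort -------------------------------------------------------


def _population(n_pos, n_neg):
    recs = []
    for i in range(n_pos):
        recs.append(make_record(patient_id=f"POS{i:02d}", note_texts=[AFFIRM]))
    for i in range(n_neg):
        recs.append(make_record(patient_id=f"NEG{i:02d}", note_texts=[NEUTRAL]))
    return recs


def test_assemble_cohort_counts_and_determinism():
    population = _population(30, 30)
    strategy = Strategy(name="notes_only")
    ids = assemble_cohort(population, strategy, 25, 25, seed=7)
    assert len(ids) == 50 and ids == sorted(ids)
    assert sum(pid.startswith("POS") for pid in ids) == 25
    assert ids == assemble_cohort(population, strategy, 25, 25, seed=7)
    assert ids != assemble_cohort(population, strategy, 25, 25, seed=8)


def test_assemble_cohort_empty_and_insufficient():
    population = _population(10, 10)
    strategy = Strategy(name="notes_only")
    assert assemble_cohort(population, strategy, 0, 0, seed=1) == []
    with pytest.raises(ValueError, match="10 strategy-positive"):
        assemble_cohort(population, strategy, 25, 5, seed=1)


# --- confusion & metrics ---------------------------------------------------


def test_confusion_all_four_cells(gold_for):
    preds = [_pred("A", True), _pred("B", True), _pred("C", False), _pred("D", False)]
    gold = gold_for({"A": True, "B": False, "C": True, "D": False})
    counts = confusion(preds, gold)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 1, 1, 1)
    assert counts.total == 4


def test_confusion_hand_enumerated(gold_for):
    preds = [_pred("A", True), _pred("B", True), _pred("C", False)]
    counts = confusion(preds, gold_for({"A": True, "B": False, "C": True}))
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (1, 1, 1, 0)


def test_confusion_missing_label_lists_patients(gold_for):
    with pytest.raises(ValueError, match="A, B"):
        confusion([_pred("A", True), _pred("B", False)], gold_for({"C": True}))


def test_metric_closed_forms():
    result = sensitivity_specificity(ConfusionCounts(tp=23, fp=0, tn=25, fn=2))
    assert result.sensitivity == pytest.approx(0.920)
    assert result.specificity == pytest.approx(1.000)
    assert result.sensitivity_ci[0] <= 0.92 <= result.sensitivity_ci[1]
    assert sensitivity_specificity(
        ConfusionCounts(tp=15, fp=0, tn=0, fn=1)
    ).sensitivity == pytest.approx(0.9375)


def test_zero_denominator_is_flagged_not_coerced():
    result = sensitivity_specificity(ConfusionCounts(tp=0, fp=3, tn=7, fn=0))
    assert not result.sensitivity_defined and result.sensitivity is None
    assert result.sensitivity_ci is None
    assert result.specificity == pytest.approx(0.7)


def test_metrics_exhaustive_margins_against_closed_form():
    """sensitivity = tp/(tp+fn) and specificity = tn/(tn+fp) on every margin
    pair with entries 0..30, with valid Wilson intervals."""
    for a, b in itertools.product(range(31), repeat=2):
        res = sensitivity_specificity(ConfusionCounts(tp=a, fp=0, tn=0, fn=b))
        if a + b == 0:
            assert res.sensitivity is None
        else:
            assert res.sensitivity == pytest.approx(a / (a + b))
            low, high = res.sensitivity_ci
            assert 0.0 <= low <= res.sensitivity <= high <= 1.0
        spec_res = sensitivity_specificity(ConfusionCounts(tp=0, fp=b, tn=a, fn=0))
        if a + b == 0:
            assert spec_res.specificity is None
        else:
            assert spec_res.specificity == pytest.approx(a / (a + b))


def test_metrics_invariant_under_patient_relabeling(gold_for):
    preds1 = [_pred("A", True), _pred("B", False), _pred("C", True)]
    preds2 = [_pred("X", True), _pred("Y", False), _pred("Z", True)]
    gold1 = gold_for({"A": True, "B": True, "C": False})
    gold2 = gold_for({"X": True, "Y": True, "Z": False})
    r1 = sensitivity_specificity(confusion(preds1, gold1))
    r2 = sensitivity_specificity(confusion(preds2, gold2))
    assert (r1.sensitivity, r1.specificity) == (r2.sensitivity, r2.specificity)


# --- compare_strategies ----------------------------------------------------


def test_compare_single_strategy_perfect_corpus(gold_for):
    population = _population(5, 5)
    gold = gold_for(
        {r.patient_id: r.patient_id.startswith("POS") for r in population}
    )
    table = compare_strategies(population, [Strategy(name="notes_only")], gold)
    assert len(table) == 1
    assert table.loc[0, "sensitivity"] == 1.0 and table.loc[0, "specificity"] == 1.0


def test_compare_empty_strategy_list_rejected(gold_for):
    with pytest.raises(ValueError):
        compare_strategies(_population(2, 2), [], gold_for({}))


def test_or_strategy_dominates_notes_only_sensitivity(gold_for):
    # notes miss one case that carries a code: OR recovers it
    population = _population(4, 4)
    population.append(
        make_record(patient_id="POSC", note_texts=[NEUTRAL], codes=[("ICD10CM", "D65", 5)])
    )
    gold = gold_for(
        {r.patient_id: r.patient_id.startswith("POS") for r in population}
    )
    strategies = [
        Strategy(name="notes_only", label="notes"),
        Strategy(name="notes_or_codes", label="or"),
    ]
    table = compare_strategies(population, strategies, gold).set_index("strategy")
    assert table.loc["or", "sensitivity"] >= table.loc["notes", "sensitivity"]
    assert table.loc["or", "sensitivity"] == 1.0


def test_exclusion_rules_trade_sensitivity_for_specificity(gold_for):
    # a control with a confounder note and a case genuinely mentioning a
    # trigger next to a partner word
    population = [
        make_record(patient_id="CTRL", note_texts=["DIC panel sent."]),
        make_record(patient_id="CASE", note_texts=["DIC present; HIT excluded."]),
    ]
    gold = gold_for({"CTRL": False, "CASE": True})
    base = TermLexicon.default().without_exclusions()
    with_rules = TermLexicon.default()
    t = compare_strategies(
        population,
        [
            Strategy(name="notes_only", lexicon=base, label="off"),
            Strategy(name="notes_only", lexicon=with_rules, label="on"),
        ],
        gold,
    ).set_index("strategy")
    assert t.loc["on", "specificity"] >= t.loc["off", "specificity"]
    assert t.loc["on", "sensitivity"] <= t.loc["off", "sensitivity"]


# --- disagreement report ---------------------------------------------------


def test_disagreements_empty_when_perfect(gold_for):
    preds = [_pred("A", True), _pred("B", False)]
    assert disagreement_report(preds, gold_for({"A": True, "B": False})) == []


def test_disagreement_directions_and_fp_evidence(gold_for):
    fp_record = make_record(patient_id="FP", note_texts=[AFFIRM])
    pred_fp = screen_patient(fp_record, Strategy(name="notes_only"))
    preds = [pred_fp, _pred("FN", False)]
    report = disagreement_report(preds, gold_for({"FP": False, "FN": True}))
    by_pid = {r["patient_id"]: r for r in report}
    assert by_pid["FP"]["direction"] == "fp"
    assert by_pid["FN"]["direction"] == "fn"
    # the fp record carries the unsuppressed mentions that caused the call
    assert any("DIC" in m for m in by_pid["FP"]["evidence_mentions"])
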