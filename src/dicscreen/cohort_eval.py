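"""Patient-level screening, cohort assembly and diagnostic-accuracy
evaluation against gold-standard labels.

A Strategy applies the note search, the code search, or their combination
(``or`` by default, ``and`` available) to each patient's records restricted
to the ICU stay window. Evaluation is the standard 2x2 table with
sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP), with 95% Wilson
score intervals; zero-denominator metrics are flagged undefined rather than
coerced.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .code_search import CodeSet, DEFAULT_CODE_SET, match_codes
from .corpus_model import CodeEvent, GoldLabel, PatientRecord
from .rule_engine import (
    DEFAULT_QUALIFIER_WINDOW,
    NotePrediction,
    TermLexicon,
    classify_note,
)

STRATEGY_NAMES = ("notes_only", "codes_only", "notes_or_codes")


@dataclass(frozen=True)
class Strategy:
    """One screening strategy: which evidence streams to consult and with
    what configuration. ``label`` is the display name used in reports."""

    name: str
    lexicon: TermLexicon = field(default_factory=TermLexicon.default)
    code_set: CodeSet = DEFAULT_CODE_SET
    combine: str = "or"
    qualifier_window: int = DEFAULT_QUALIFIER_WINDOW
    label: str = ""

    def __post_init__(self) -> None:
        if self.name not in STRATEGY_NAMES:
            raise ValueError(f"strategy name {self.name!r} not one of {STRATEGY_NAMES}")
        if self.combine not in ("or", "and"):
            raise ValueError("combine must be 'or' or 'and'")
        if not self.label:
            object.__setattr__(self, "label", self.name)


def default_strategies() -> list[Strategy]:
    """The three searches compared in the study design: the original
    notes-plus-codes screen (no exclusion rules), codes alone, and the
    revised notes-only search with the five exclusion rules."""
    base = TermLexicon.default()
    return [
        Strategy(
            name="notes_or_codes",
            lexicon=base.without_exclusions(),
            label="Clinical Notes and Diagnosis Codes",
        ),
        Strategy(name="codes_only", label="Diagnostic Codes only"),
        Strategy(name="notes_only", lexicon=base, label="Revised Clinical Notes"),
    ]


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    strategy: str
    positive: bool
    evidence_note_ids: tuple[str, ...] = ()
    evidence_codes: tuple[CodeEvent, ...] = ()
    note_predictions: tuple[NotePrediction, ...] = ()  # audit trail, all in-window notes

    def __post_init__(self) -> None:
        has_evidence = bool(self.evidence_note_ids) or bool(self.evidence_codes)
        if self.positive != has_evidence:
            raise ValueError("positive flag inconsistent with evidence")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricResult:
    """Sensitivity/specificity with 95% Wilson CIs.

    A metric with a zero denominator is undefined: its value and CI are None
    and the corresponding ``*_defined`` flag is False.
    """

    counts: ConfusionCounts
    sensitivity: float | None
    sensitivity_ci: tuple[float, float] | None
    specificity: float | None
    specificity_ci: tuple[float, float] | None

    @property
    def n_pos(self) -> int:
        return self.counts.tp + self.counts.fn

    @property
    def n_neg(self) -> int:
        return self.counts.tn + self.counts.fp

    @property
    def sensitivity_defined(self) -> bool:
        return self.sensitivity is not None

    @property
    def specificity_defined(self) -> bool:
        return self.specificity is not None


def _note_in_window(note, stays) -> bool:
    return any(s.admit_ts <= note.timestamp <= s.discharge_ts for s in stays)


def screen_patient(record: PatientRecord, strategy: Strategy) -> PatientPrediction:
    """Apply one strategy to one patient.

    Only notes timestamped inside an ICU stay (inclusive) are classified;
    out-of-window notes are ignored. A record with no stays raises.
    """
    if not record.stays:
        raise ValueError(
            f"patient {record.patient_id!r} has no ICU stays; record unusable"
        )

    note_preds: tuple[NotePrediction, ...] = ()
    positive_note_ids: tuple[str, ...] = ()
    if strategy.name in ("notes_only", "notes_or_codes"):
        in_window = [n for n in record.notes if _note_in_window(n, record.stays)]
        note_preds = tuple(
            classify_note(n, strategy.lexicon, window=strategy.qualifier_window)
            for n in in_window
        )
        positive_note_ids = tuple(p.note_id for p in note_preds if p.positive)

    code_hit, code_events = False, []
    if strategy.name in ("codes_only", "notes_or_codes"):
        code_hit, code_events = match_codes(record, strategy.code_set)

    if strategy.name == "notes_only":
        positive = bool(positive_note_ids)
    elif strategy.name == "codes_only":
        positive = code_hit
    elif strategy.combine == "or":
        positive = bool(positive_note_ids) or code_hit
    else:
        positive = bool(positive_note_ids) and code_hit

    return PatientPrediction(
        patient_id=record.patient_id,
        strategy=strategy.label,
        positive=positive,
        evidence_note_ids=positive_note_ids if positive else (),
        evidence_codes=tuple(code_events) if positive else (),
        note_predictions=note_preds,
    )


def screen_population(
    population: Sequence[PatientRecord], strategy: Strategy
) -> list[PatientPrediction]:
    """Screen every patient possessing at least one stay."""
    return [screen_patient(r, strategy) for r in population if r.stays]


def assemble_cohort(
    population: Sequence[PatientRecord],
    strategy: Strategy,
    n_meeting: int,
    n_not: int,
    seed: int,
) -> list[str]:
    """Sample a study cohort: ``n_meeting`` strategy-positive patients and
    ``n_not`` strategy-negative ones, uniformly without replacement.
    Deterministic given the seed; returned ids are sorted."""
    preds = screen_population(population, strategy)
    positives = [p.patient_id for p in preds if p.positive]
    negatives = [p.patient_id for p in preds if not p.positive]
    if len(positives) < n_meeting or len(negatives) < n_not:
        raise ValueError(
            f"insufficient patients: {len(positives)} strategy-positive "
            f"(need {n_meeting}), {len(negatives)} strategy-negative (need {n_not})"
        )
    rng = random.Random(seed)
    chosen = rng.sample(positives, n_meeting) + rng.sample(negatives, n_not)
    return sorted(chosen)


def _gold_map(gold: Iterable[GoldLabel] | Mapping[str, bool]) -> dict[str, bool]:
    if isinstance(gold, Mapping):
        return dict(gold)
    return {g.patient_id: g.dic_status for g in gold}


def confusion(
    predictions: Sequence[PatientPrediction],
    gold: Iterable[GoldLabel] | Mapping[str, bool],
) -> ConfusionCounts:
    """Tally the 2x2 table; every predicted patient must carry a gold label."""
    labels = _gold_map(gold)
    missing = sorted(p.patient_id for p in predictions if p.patient_id not in labels)
    if missing:
        raise ValueError(f"missing gold label(s) for patient(s): {', '.join(missing)}")
    tp = fp = tn = fn = 0
    for p in predictions:
        truth = labels[p.patient_id]
        if p.positive and truth:
            tp += 1
        elif p.positive and not truth:
            fp += 1
        elif not p.positive and not truth:
            tn += 1
        else:
            fn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _wilson(successes: int, total: int) -> tuple[float, tuple[float, float]]:
    low, high = proportion_confint(successes, total, alpha=0.05, method="wilson")
    point = successes / total
    # guard against float dust at the boundary (count 0 or count == total)
    return point, (min(float(low), point), max(float(high), point))


def sensitivity_specificity(counts: ConfusionCounts) -> MetricResult:
    """Point estimates and 95% Wilson score intervals from a 2x2 table."""
    if counts.tp + counts.fn > 0:
        sens, sens_ci = _wilson(counts.tp, counts.tp + counts.fn)
    else:
        sens, sens_ci = None, None
    if counts.tn + counts.fp > 0:
        spec, spec_ci = _wilson(counts.tn, counts.tn + counts.fp)
    else:
        spec, spec_ci = None, None
    return MetricResult(
        counts=counts,
        sensitivity=sens,
        sensitivity_ci=sens_ci,
        specificity=spec,
        specificity_ci=spec_ci,
    )


def evaluate_strategy(
    population: Sequence[PatientRecord],
    strategy: Strategy,
    gold: Iterable[GoldLabel] | Mapping[str, bool],
    cohort_ids: Sequence[str] | None = None,
) -> tuple[MetricResult, list[PatientPrediction]]:
    """Screen (optionally a sub-cohort of) the population and evaluate."""
    if cohort_ids is not None:
        wanted = set(cohort_ids)
        population = [r for r in population if r.patient_id in wanted]
    preds = screen_population(population, strategy)
    return sensitivity_specificity(confusion(preds, gold)), preds


def compare_strategies(
    population: Sequence[PatientRecord],
    strategies: Sequence[Strategy],
    gold: Iterable[GoldLabel] | Mapping[str, bool],
    n_meeting: int | None = None,
    n_not: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every strategy on one shared cohort and tabulate the rows.

    The cohort is assembled under the first strategy (``n_meeting``
    strategy-positive + ``n_not`` strategy-negative patients); with both
    None the whole population is used.
    """
    if not strategies:
        raise ValueError("at least one strategy required")
    if n_meeting is None and n_not is None:
        cohort_ids = None
    else:
        cohort_ids = assemble_cohort(
            population, strategies[0], n_meeting or 0, n_not or 0, seed
        )
    rows = []
    for strategy in strategies:
        metrics, _ = evaluate_strategy(population, strategy, gold, cohort_ids)
        c = metrics.counts
        rows.append(
            {
                "strategy": strategy.label,
                "sensitivity": metrics.sensitivity,
                "sens_ci_low": metrics.sensitivity_ci[0] if metrics.sensitivity_ci else None,
                "sens_ci_high": metrics.sensitivity_ci[1] if metrics.sensitivity_ci else None,
                "specificity": metrics.specificity,
                "spec_ci_low": metrics.specificity_ci[0] if metrics.specificity_ci else None,
                "spec_ci_high": metrics.specificity_ci[1] if metrics.specificity_ci else None,
                "tp": c.tp,
                "fp": c.fp,
                "tn": c.tn,
                "fn": c.fn,
                "n_pos": metrics.n_pos,
                "n_neg": metrics.n_neg,
            }
        )
    return pd.DataFrame(rows)


def format_comparison(table: pd.DataFrame) -> str:
    """Pretty text rendering of the strategy-comparison table."""
    lines = [f"{'Strategy':<40} {'Sensitivity':>12} {'Specificity':>12}"]
    for _, row in table.iterrows():
        sens = "undef" if pd.isna(row["sensitivity"]) else f"{row['sensitivity']:.1%}"
        spec = "undef" if pd.isna(row["specificity"]) else f"{row['specificity']:.1%}"
        lines.append(f"{row['strategy']:<40} {sens:>12} {spec:>12}")
    return "\n".join(lines)


def disagreement_report(
    predictions: Sequence[PatientPrediction],
    gold: Iterable[GoldLabel] | Mapping[str, bool],
) -> list[dict]:
    """One record per false positive / false negative, with the evidence
    trail (unsuppressed mentions and matching codes) to support manual
    adjudication of the disagreement."""
    labels = _gold_map(gold)
    confusion(predictions, labels)  # raises on missing labels
    report = []
    for p in predictions:
        truth = labels[p.patient_id]
        if p.positive == truth:
            continue
        mention_trail = [
            f"{np.note_id}:{m.term}[{m.char_start}:{m.char_end}]"
            for np in p.note_predictions
            for m in np.mentions
            if not m.suppressed
        ]
        code_trail = [f"{e.code_system}:{e.code}" for e in p.evidence_codes]
        report.append(
            {
                "patient_id": p.patient_id,
                "strategy": p.strategy,
                "predicted": p.positive,
                "gold": truth,
                "direction": "fp" if p.positive else "fn",
                "evidence_mentions": mention_trail,
                "evidence_codes": code_trail,
            }
        )
    return report
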