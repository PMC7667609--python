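"""Seeded generator of synthetic ICU corpora with a latent DIC status.

Real ICU notes are private, so every other module is exercised against
templated synthetic notes that reproduce the phenomena the search must
discriminate: affirmative DIC mentions, qualifier-negated mentions ("no
evidence of DIC"), and the confounder contexts targeted by the exclusion
rules ("DIC panel", "DIC profile", "DIC vs HIT", fibrinolysis in liver
disease or cirrhosis). Templates are deliberately unambiguous under the
rule engine's documented scoping defaults, so the expected output of a
correct engine can be derived from template provenance alone and used as
an exact end-to-end oracle.

Gold labels come from the latent status and stand in for manual chart
review; laboratory values are not simulated.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path

from .corpus_model import (
    ClinicalNote,
    CodeEvent,
    GoldLabel,
    ICUStay,
    PatientRecord,
    write_notes,
    write_table,
)
from .rule_engine import TermLexicon

CONFOUNDER_CLASSES = (
    "dic_panel",
    "dic_profile",
    "hit_context",
    "fibrinolysis_liver",
    "fibrinolysis_cirrhosis",
)

# confounder class -> (trigger term, partner phrase) its payload instantiates
CLASS_RULE_PAIRS = {
    "dic_panel": ("DIC", "panel"),
    "dic_profile": ("DIC", "profile"),
    "hit_context": ("DIC", "HIT"),
    "fibrinolysis_liver": ("fibrinolysis", "liver disease"),
    "fibrinolysis_cirrhosis": ("fibrinolysis", "cirrhosis"),
}

# payload variants; negated variants carry the qualifier phrase they use
AFFIRMATIVE_VARIANTS = (
    "Overt DIC with ongoing bleeding is present.",
    "Findings are consistent with disseminated intravascular coagulation.",
    "Clinical course now complicated by disseminated intravascular coagulopathy.",
    "Laboratory picture supports consumptive coagulopathy.",
    "Smear and coags indicate consumption coagulopathy.",
)
NEGATED_VARIANTS = (
    ("No evidence of DIC today.", "no"),
    ("Coagulation screen negative for DIC.", "negative"),
    ("History of DIC during a prior admission.", "history"),
    ("We have ruled out DIC for this admission.", "ruled out"),
)
CONFOUNDER_VARIANTS = {
    "dic_panel": (
        "DIC panel sent this morning.",
        "Will send DIC panel with morning labs.",
        "DIC panel results pending at this time.",
    ),
    "dic_profile": (
        "DIC profile ordered.",
        "Repeat DIC profile in the morning.",
        "DIC profile within expected limits.",
    ),
    "hit_context": (
        "Thrombocytopenia differential includes DIC vs HIT.",
        "DIC vs HIT remains the main consideration.",
        "Unable to distinguish DIC from HIT at this point.",
    ),
    "fibrinolysis_liver": (
        "Fibrinolysis attributed to underlying liver disease.",
        "Fibrinolysis in the context of advanced liver disease.",
        "Liver disease with associated fibrinolysis.",
    ),
    "fibrinolysis_cirrhosis": (
        "Fibrinolysis likely reflects known cirrhosis.",
        "Cirrhosis with accelerated fibrinolysis.",
        "Fibrinolysis felt secondary to cirrhosis.",
    ),
}
# filler avoids every include term, qualifier term and exclusion partner
FILLER_SENTENCES = (
    "Patient remains stable on current support.",
    "Vital signs reviewed overnight with the team.",
    "Plan discussed with the family at bedside.",
    "Continue current management and monitoring.",
    "Morning labs reviewed and follow up planned.",
    "Sedation weaned as tolerated today.",
)

TEMPLATE_CLASSES = ("affirmative", "negated", "neutral") + CONFOUNDER_CLASSES


@dataclass(frozen=True)
class SimParams:
    """Generator settings; the defaults mirror the 25/25 cohort design."""

    n_patients: int = 50
    prevalence: float = 0.5
    notes_per_patient: tuple[int, int] = (1, 5)
    p_affirm_mention_if_case: float = 0.95
    p_negated_mention_if_control: float = 0.2
    p_confounder_note: dict = field(
        default_factory=lambda: {c: 0.1 for c in CONFOUNDER_CLASSES}
    )
    p_code_if_case: float = 0.6
    p_code_if_control: float = 0.02
    p_note_outside_stay: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        lo, hi = self.notes_per_patient
        if not (1 <= lo <= hi):
            raise ValueError("notes_per_patient must satisfy 1 <= lo <= hi")
        proportions = {
            "prevalence": self.prevalence,
            "p_affirm_mention_if_case": self.p_affirm_mention_if_case,
            "p_negated_mention_if_control": self.p_negated_mention_if_control,
            "p_code_if_case": self.p_code_if_case,
            "p_code_if_control": self.p_code_if_control,
            "p_note_outside_stay": self.p_note_outside_stay,
            **{f"p_confounder_note[{k}]": v for k, v in self.p_confounder_note.items()},
        }
        for name, value in proportions.items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        unknown = set(self.p_confounder_note) - set(CONFOUNDER_CLASSES)
        if unknown:
            raise ValueError(f"unknown confounder class(es): {sorted(unknown)}")


def render_note(template_class: str, rng: random.Random) -> tuple[str, dict]:
    """Compose one note: the class payload sentence framed by 0-2 neutral
    filler sentences on each side. Returns the text and a provenance record
    tagging every sentence with the template class that produced it."""
    if template_class not in TEMPLATE_CLASSES:
        raise ValueError(f"unknown template class {template_class!r}")
    qualifier = None
    if template_class == "affirmative":
        payload = rng.choice(AFFIRMATIVE_VARIANTS)
    elif template_class == "negated":
        payload, qualifier = rng.choice(NEGATED_VARIANTS)
    elif template_class == "neutral":
        payload = rng.choice(FILLER_SENTENCES)
    else:
        payload = rng.choice(CONFOUNDER_VARIANTS[template_class])

    lead = [rng.choice(FILLER_SENTENCES) for _ in range(rng.randint(0, 2))]
    tail = [rng.choice(FILLER_SENTENCES) for _ in range(rng.randint(0, 2))]
    payload_class = "neutral" if template_class == "neutral" else template_class
    sentences = (
        [{"class": "filler", "text": s} for s in lead]
        + [{"class": payload_class, "text": payload}]
        + [{"class": "filler", "text": s} for s in tail]
    )
    text = " ".join(s["text"] for s in sentences)
    provenance = {
        "template_class": template_class,
        "payload": payload,
        "qualifier": qualifier,
        "sentences": sentences,
    }
    return text, provenance


def _note_classes(is_case: bool, params: SimParams, rng: random.Random) -> list[str]:
    classes: list[str] = []
    if is_case:
        if rng.random() < params.p_affirm_mention_if_case:
            classes.append("affirmative")
    else:
        if rng.random() < params.p_negated_mention_if_control:
            classes.append("negated")
        for cls in CONFOUNDER_CLASSES:
            if rng.random() < params.p_confounder_note.get(cls, 0.0):
                classes.append(cls)
    lo, hi = params.notes_per_patient
    target = rng.randint(lo, hi)
    while len(classes) < target:
        classes.append("neutral")
    rng.shuffle(classes)
    return classes


def generate_cohort(
    params: SimParams,
) -> tuple[list[PatientRecord], list[GoldLabel], list[dict]]:
    """Generate a synthetic cohort: patient records (one ICU stay each),
    latent gold labels, and per-note template provenance ("truth").

    Byte-identical output for identical parameters and seed. When
    ``prevalence * n_patients`` is integral the case count is hit exactly.
    """
    rng = random.Random(params.seed)
    n = params.n_patients
    expected = params.prevalence * n
    if abs(expected - round(expected)) < 1e-9:
        case_ids = set(rng.sample(range(n), int(round(expected))))
        statuses = [i in case_ids for i in range(n)]
    else:
        statuses = [rng.random() < params.prevalence for i in range(n)]

    base = datetime(2015, 1, 1, tzinfo=timezone.utc)
    records: list[PatientRecord] = []
    labels: list[GoldLabel] = []
    truth: list[dict] = []
    for i in range(n):
        pid = f"P{i:04d}"
        is_case = statuses[i]
        admit = base + timedelta(days=2 * i)
        discharge = admit + timedelta(days=3)
        stay = ICUStay(pid, f"S{i:04d}", admit, discharge)
        duration = (discharge - admit).total_seconds()

        notes: list[ClinicalNote] = []
        for j, cls in enumerate(_note_classes(is_case, params, rng)):
            text, provenance = render_note(cls, rng)
            outside = rng.random() < params.p_note_outside_stay
            if outside:
                ts = admit - timedelta(days=1, seconds=int(rng.random() * 3600))
            else:
                ts = admit + timedelta(seconds=int(rng.random() * duration))
            note_id = f"{pid}-N{j:02d}"
            notes.append(ClinicalNote(pid, note_id, ts, text))
            truth.append(
                {
                    "patient_id": pid,
                    "note_id": note_id,
                    "in_stay": not outside,
                    **provenance,
                }
            )

        codes: list[CodeEvent] = []
        p_code = params.p_code_if_case if is_case else params.p_code_if_control
        if rng.random() < p_code:
            codes.append(
                CodeEvent(pid, "D65", "ICD10CM", admit + timedelta(hours=12))
            )

        records.append(PatientRecord(pid, stays=[stay], notes=notes, codes=codes))
        labels.append(GoldLabel(pid, is_case, source="synthetic_latent"))
    return records, labels, truth


def expected_oracle_labels(truth: list[dict], lexicon: TermLexicon) -> dict[str, bool]:
    """Expected note-search output per patient, derived from template
    provenance alone (no text parsing).

    A note contributes a positive only if it is inside the stay and its
    payload survives the lexicon: affirmative always does; a negated payload
    survives only if its qualifier is absent from the lexicon; a confounder
    payload survives only if no exclusion rule covers its trigger/partner
    pair; neutral never does.
    """
    qualifiers = {q.lower() for q in lexicon.qualifier_terms}
    covered = {
        (r.trigger_term, r.partner_phrase.lower()) for r in lexicon.exclusion_rules
    }
    expected: dict[str, bool] = {}
    for rec in truth:
        pid = rec["patient_id"]
        expected.setdefault(pid, False)
        if not rec["in_stay"]:
            continue
        cls = rec["template_class"]
        if cls == "affirmative":
            positive = True
        elif cls == "negated":
            positive = rec["qualifier"].lower() not in qualifiers
        elif cls in CLASS_RULE_PAIRS:
            trigger, partner = CLASS_RULE_PAIRS[cls]
            positive = (trigger, partner.lower()) not in covered
        else:
            positive = False
        expected[pid] = expected[pid] or positive
    return expected


CORPUS_FILES = ("notes.jsonl", "stays.csv", "codes.csv", "gold.csv", "truth.jsonl")


def write_corpus(
    directory: str | Path,
    records: list[PatientRecord],
    labels: list[GoldLabel],
    truth: list[dict],
) -> list[Path]:
    """Write the standard corpus files into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    notes = [n for r in records for n in r.notes]
    stays = [s for r in records for s in r.stays]
    codes = [c for r in records for c in r.codes]
    write_notes(notes, directory / "notes.jsonl")
    write_table(stays, directory / "stays.csv", "stays")
    write_table(codes, directory / "codes.csv", "codes")
    write_table(labels, directory / "gold.csv", "gold")
    with (directory / "truth.jsonl").open("w", encoding="utf-8") as handle:
        for rec in truth:
            handle.write(json.dumps(rec, ensure_ascii=False, sort_keys=True) + "\n")
    return [directory / name for name in CORPUS_FILES]


def read_truth(path: str | Path) -> list[dict]:
    with Path(path).open(encoding="utf-8") as handle:
        return [json.loads(line) for line in handle if line.strip()]
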