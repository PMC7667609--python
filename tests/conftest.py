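"""Shared fixtures: a default lexicon, small corpus builders and a seeded
random note-text generator that mixes lexicon phrases, qualifiers,
exclusion partners and neutral filler."""

from __future__ import annotations

import random
from datetime import datetime, timedelta, timezone

import pytest

from dicscreen import ClinicalNote, CodeEvent, GoldLabel, ICUStay, PatientRecord, TermLexicon

UTC = timezone.utc

# phrase soup for random note generation: every behaviourally distinct
# category is represented, including case variants of the DIC acronym
VOCAB_PIECES = [
    "DIC",
    "dic",
    "Dic",
    "disseminated intravascular coagulation",
    "Disseminated Intravascular Coagulopathy",
    "defibrination syndrome",
    "intravascular coagulopathy",
    "consumption coagulopathy",
    "consumptive coagulopathy",
    "fibrinolysis",
    "Fibrinolysis",
    "no",
    "No",
    "negative",
    "history",
    "ruled out",
    "panel",
    "profile",
    "HIT",
    "hit",
    "liver disease",
    "liver",
    "cirrhosis",
    "patient",
    "stable",
    "bleeding",
    "evidence",
    "of",
    "for",
    "the",
    "today",
    "dichotomized",
    "anticoagulation",
]
SEPARATORS = [" ", " ", " ", " ", ". ", ".\n", "\n", "; ", ", ", " - ", "/"]


def random_note_text(rng: random.Random, max_pieces: int = 25) -> str:
    """Compose adversarial note text from the phrase soup (<= ~60 tokens)."""
    n = rng.randint(0, max_pieces)
    parts = []
    for i in range(n):
        parts.append(rng.choice(VOCAB_PIECES))
        if i < n - 1:
            parts.append(rng.choice(SEPARATORS))
    return "".join(parts)


@pytest.fixture
def lexicon() -> TermLexicon:
    return TermLexicon.default()


@pytest.fixture
def t0() -> datetime:
    return datetime(2015, 6, 1, tzinfo=UTC)


def make_record(
    patient_id: str = "P1",
    note_texts: list[str] | None = None,
    note_offsets_h: list[int] | None = None,
    codes: list[tuple[str, str, int]] | None = None,
    stay_hours: int = 72,
    t0: datetime = datetime(2015, 6, 1, tzinfo=UTC),
) -> PatientRecord:
    """One-patient record with a single stay; note/code timestamps are given
    as hour offsets from admission (may be negative or past discharge)."""
    stay = ICUStay(patient_id, f"{patient_id}-S", t0, t0 + timedelta(hours=stay_hours))
    texts = note_texts or []
    offsets = note_offsets_h or [1] * len(texts)
    notes = [
        ClinicalNote(patient_id, f"{patient_id}-N{i}", t0 + timedelta(hours=off), text)
        for i, (text, off) in enumerate(zip(texts, offsets))
    ]
    code_events = [
        CodeEvent(patient_id, code, system, t0 + timedelta(hours=off))
        for system, code, off in (codes or [])
    ]
    return PatientRecord(patient_id, stays=[stay], notes=notes, codes=code_events)


@pytest.fixture
def gold_for():
    def _gold(statuses: dict[str, bool]) -> list[GoldLabel]:
        return [
            GoldLabel(pid, status, source="synthetic_latent")
            for pid, status in statuses.items()
        ]

    return _gold
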