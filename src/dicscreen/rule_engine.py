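"""The electronic DIC search algorithm over a single clinical note.

The pipeline is: tokenize the note, locate include-term mentions
(whole-word, longest match wins), suppress mentions preceded in-sentence by
a qualifier ("no", "negative", "history", "ruled out"), then suppress
trigger terms whose exclusion partner co-occurs anywhere in the note
("DIC panel", "DIC profile", "DIC vs HIT", fibrinolysis with liver
disease or cirrhosis). A note is positive iff at least one mention survives.
Suppression only flags mentions — nothing is deleted, so every prediction
carries a full audit trail.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .corpus_model import ClinicalNote

DEFAULT_INCLUDE_TERMS = (
    "disseminated intravascular coagulation",
    "disseminated intravascular coagulopathy",
    "DIC",
    "defibrination syndrome",
    "intravascular coagulopathy",
    "consumption coagulopathy",
    "consumptive coagulopathy",
    "fibrinolysis",
)

DEFAULT_QUALIFIER_TERMS = ("no", "negative", "history", "ruled out")

# (rule_id, trigger include term, partner phrase)
DEFAULT_EXCLUSION_PAIRS = (
    ("fibrinolysis_liver_disease", "fibrinolysis", "liver disease"),
    ("fibrinolysis_cirrhosis", "fibrinolysis", "cirrhosis"),
    ("dic_panel", "DIC", "panel"),
    ("dic_profile", "DIC", "profile"),
    ("dic_hit", "DIC", "HIT"),
)

DEFAULT_QUALIFIER_WINDOW = 5

SENTENCE_DELIMITERS = frozenset(".!?\n")


@dataclass(frozen=True)
class ExclusionRule:
    """Suppress ``trigger_term`` mentions when ``partner_phrase`` occurs
    anywhere in the same note (whole-word, case-insensitive)."""

    rule_id: str
    trigger_term: str
    partner_phrase: str

    def __post_init__(self) -> None:
        if not self.rule_id or not self.trigger_term or not self.partner_phrase:
            raise ValueError("exclusion rule fields must be non-empty")


def _normalize_phrase(phrase: str) -> str:
    return " ".join(phrase.split())


@dataclass(frozen=True)
class TermLexicon:
    """The algorithm's configuration: include phrases, qualifier phrases and
    co-occurrence exclusion rules."""

    include_terms: tuple[str, ...] = DEFAULT_INCLUDE_TERMS
    qualifier_terms: tuple[str, ...] = DEFAULT_QUALIFIER_TERMS
    exclusion_rules: tuple[ExclusionRule, ...] = tuple(
        ExclusionRule(*pair) for pair in DEFAULT_EXCLUSION_PAIRS
    )

    def __post_init__(self) -> None:
        include = tuple(_normalize_phrase(t) for t in self.include_terms)
        qualifiers = tuple(_normalize_phrase(t) for t in self.qualifier_terms)
        if any(not t for t in include) or any(not t for t in qualifiers):
            raise ValueError("lexicon phrases must be non-empty")
        if len(set(include)) != len(include):
            raise ValueError("duplicate include terms")
        object.__setattr__(self, "include_terms", include)
        object.__setattr__(self, "qualifier_terms", qualifiers)
        object.__setattr__(self, "exclusion_rules", tuple(self.exclusion_rules))
        for rule in self.exclusion_rules:
            if rule.trigger_term not in include:
                raise ValueError(
                    f"exclusion rule {rule.rule_id!r}: trigger {rule.trigger_term!r} "
                    "is not an include term"
                )

    @classmethod
    def default(cls) -> "TermLexicon":
        return cls()

    def without_exclusions(self) -> "TermLexicon":
        """The un-refined search: same terms, no co-occurrence rules."""
        return replace(self, exclusion_rules=())

    def with_rule(self, rule: ExclusionRule) -> "TermLexicon":
        return replace(self, exclusion_rules=self.exclusion_rules + (rule,))

    def to_dict(self) -> dict:
        return {
            "include_terms": list(self.include_terms),
            "qualifier_terms": list(self.qualifier_terms),
            "exclusion_rules": [
                {"rule_id": r.rule_id, "trigger": r.trigger_term, "partner": r.partner_phrase}
                for r in self.exclusion_rules
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "TermLexicon":
        return cls(
            include_terms=tuple(data["include_terms"]),
            qualifier_terms=tuple(data["qualifier_terms"]),
            exclusion_rules=tuple(
                ExclusionRule(r["rule_id"], r["trigger"], r["partner"])
                for r in data.get("exclusion_rules", [])
            ),
        )


@dataclass(frozen=True)
class Token:
    surface: str
    char_start: int
    char_end: int
    sentence_index: int


@dataclass(frozen=True)
class TokenizedNote:
    note_id: str
    text: str
    tokens: tuple[Token, ...]


@dataclass(frozen=True)
class Mention:
    """A located include-term hit, possibly suppressed with a reason.

    ``suppression_reason`` is ``"none"``, ``"qualifier:<term>"`` or
    ``"exclusion:<rule_id>"``; ``suppressed`` is true iff the reason is not
    ``"none"``.
    """

    note_id: str
    term: str
    char_start: int
    char_end: int
    token_start: int
    token_end: int  # half-open token span
    sentence_index: int
    suppressed: bool = False
    suppression_reason: str = "none"

    def __post_init__(self) -> None:
        if self.suppressed != (self.suppression_reason != "none"):
            raise ValueError("suppressed flag inconsistent with suppression_reason")


@dataclass(frozen=True)
class NotePrediction:
    note_id: str
    positive: bool
    mentions: tuple[Mention, ...]


def tokenize(text: str, note_id: str = "") -> TokenizedNote:
    """Split text into maximal alphanumeric runs with character offsets.

    Sentence boundaries are '.', '!', '?' and newline; a run of boundary
    characters counts once (the sentence index only advances if a token was
    emitted since the previous boundary). Hyphen and '/' split tokens like
    any other non-alphanumeric character.
    """
    tokens: list[Token] = []
    sentence = 0
    emitted_in_sentence = False
    i = 0
    n = len(text)
    while i < n:
        ch = text[i]
        if ch.isalnum():
            j = i
            while j < n and text[j].isalnum():
                j += 1
            tokens.append(Token(text[i:j], i, j, sentence))
            emitted_in_sentence = True
            i = j
        else:
            if ch in SENTENCE_DELIMITERS and emitted_in_sentence:
                sentence += 1
                emitted_in_sentence = False
            i += 1
    return TokenizedNote(note_id=note_id, text=text, tokens=tuple(tokens))


def _case_sensitive_term(phrase_toks: tuple[str, ...]) -> bool:
    # Acronyms ("DIC") must appear as the exact all-caps standalone token;
    # multi-word terms match case-insensitively.
    return len(phrase_toks) == 1 and phrase_toks[0].isupper()


def _phrase_occurrences(
    tokens: Sequence[Token], phrase: str, case_sensitive: bool | None = None
) -> list[tuple[int, int]]:
    """All whole-word occurrences of ``phrase`` as half-open token spans."""
    ptoks = tuple(t.surface for t in tokenize(phrase).tokens)
    if not ptoks:
        return []
    if case_sensitive is None:
        case_sensitive = _case_sensitive_term(ptoks)
    if not case_sensitive:
        ptoks = tuple(p.lower() for p in ptoks)
    spans = []
    k = len(ptoks)
    for i in range(len(tokens) - k + 1):
        window = tuple(t.surface for t in tokens[i : i + k])
        if not case_sensitive:
            window = tuple(w.lower() for w in window)
        if window == ptoks:
            spans.append((i, i + k))
    return spans


def find_mentions(note: TokenizedNote, lexicon: TermLexicon) -> list[Mention]:
    """Locate every include-term occurrence; none suppressed yet.

    When occurrences overlap, the longest (in tokens) wins; ties break by
    lexicon order. Output is sorted by position.
    """
    candidates: list[tuple[int, int, int, str]] = []  # (start, end, lex_index, term)
    for lex_index, term in enumerate(lexicon.include_terms):
        for start, end in _phrase_occurrences(note.tokens, term):
            candidates.append((start, end, lex_index, term))

    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen: list[tuple[int, int, int, str]] = []
    for cand in candidates:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])

    mentions = []
    for start, end, _lex, term in chosen:
        first, last = note.tokens[start], note.tokens[end - 1]
        mentions.append(
            Mention(
                note_id=note.note_id,
                term=term,
                char_start=first.char_start,
                char_end=last.char_end,
                token_start=start,
                token_end=end,
                sentence_index=first.sentence_index,
            )
        )
    return mentions


def apply_qualifiers(
    mentions: Sequence[Mention],
    note: TokenizedNote,
    lexicon: TermLexicon,
    window: int = DEFAULT_QUALIFIER_WINDOW,
) -> list[Mention]:
    """Suppress mentions preceded by a qualifier phrase in the same sentence.

    A qualifier suppresses a mention when its last token lies among the
    ``window`` tokens immediately before the mention's first token. With
    window 0 nothing is suppressed. Mention order is preserved.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    qualifier_spans: list[tuple[int, int, str]] = []
    for term in lexicon.qualifier_terms:
        for start, end in _phrase_occurrences(note.tokens, term, case_sensitive=False):
            qualifier_spans.append((start, end, term))

    out = []
    for mention in mentions:
        if mention.suppressed:
            out.append(mention)
            continue
        reason = None
        for qstart, qend, term in sorted(qualifier_spans):
            if qend > mention.token_start:
                continue  # must precede the mention
            if note.tokens[qend - 1].sentence_index != mention.sentence_index:
                continue
            if mention.token_start - qend < window:
                reason = f"qualifier:{term}"
                break
        if reason:
            out.append(replace(mention, suppressed=True, suppression_reason=reason))
        else:
            out.append(mention)
    return out


def apply_exclusions(
    mentions: Sequence[Mention], note: TokenizedNote, lexicon: TermLexicon
) -> list[Mention]:
    """Apply the co-occurrence exclusion rules.

    For each rule whose partner phrase occurs anywhere in the note
    (whole-word, case-insensitive), every still-unsuppressed mention of the
    trigger term is suppressed; other include terms are never affected.
    Rules apply in lexicon order, so the first matching rule names the reason.
    """
    active: list[ExclusionRule] = [
        rule
        for rule in lexicon.exclusion_rules
        if _phrase_occurrences(note.tokens, rule.partner_phrase, case_sensitive=False)
    ]
    out = []
    for mention in mentions:
        if not mention.suppressed:
            for rule in active:
                if mention.term == rule.trigger_term:
                    mention = replace(
                        mention,
                        suppressed=True,
                        suppression_reason=f"exclusion:{rule.rule_id}",
                    )
                    break
        out.append(mention)
    return out


def classify_note(
    note: ClinicalNote | str,
    lexicon: TermLexicon | None = None,
    window: int = DEFAULT_QUALIFIER_WINDOW,
) -> NotePrediction:
    """Run the full pipeline on one note.

    Positive iff at least one mention survives both suppression passes.
    Suppressed mentions are retained for audit.
    """
    lexicon = lexicon or TermLexicon.default()
    if isinstance(note, ClinicalNote):
        text, note_id = note.text, note.note_id
    else:
        text, note_id = note, ""
    tokenized = tokenize(text, note_id=note_id)
    mentions = find_mentions(tokenized, lexicon)
    mentions = apply_qualifiers(mentions, tokenized, lexicon, window=window)
    mentions = apply_exclusions(mentions, tokenized, lexicon)
    positive = any(not m.suppressed for m in mentions)
    return NotePrediction(note_id=note_id, positive=positive, mentions=tuple(mentions))
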