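"""Independent brute-force applier of the note-search rules.

Used as the oracle for the rule engine: it enumerates every phrase
occurrence with regexes over raw character offsets and applies the
documented suppression semantics literally, sharing no code with the
token-scanning implementation in the package.
"""

from __future__ import annotations

import re

WORD = re.compile(r"[0-9A-Za-z]+")
DELIMS = ".!?\n"


def _tokens(text):
    return [(m.group(), m.start(), m.end()) for m in WORD.finditer(text)]


def _sentence_ids(text, tokens):
    """Sentence id per token: index among token-containing segments after
    splitting at every '.', '!', '?' or newline."""
    bounds = []
    start = 0
    for i, ch in enumerate(text):
        if ch in DELIMS:
            bounds.append((start, i))
            start = i + 1
    bounds.append((start, len(text)))
    ids = []
    sid = -1
    prev_seg = None
    for _surf, s, _e in tokens:
        seg = next(k for k, (a, b) in enumerate(bounds) if a <= s < b)
        if seg != prev_seg:
            sid += 1
            prev_seg = seg
        ids.append(sid)
    return ids


def _phrase_words(phrase):
    return WORD.findall(phrase)


def _occurrences(tokens, phrase, force_case_insensitive=False):
    """Whole-word occurrences of a phrase as half-open token spans. A
    single-word all-caps phrase (an acronym like DIC) matches
    case-sensitively unless forced otherwise."""
    words = _phrase_words(phrase)
    if not words:
        return []
    sensitive = (
        not force_case_insensitive and len(words) == 1 and words[0].isupper()
    )
    if not sensitive:
        words = [w.lower() for w in words]
    spans = []
    for i in range(len(tokens) - len(words) + 1):
        surfaces = [t[0] for t in tokens[i : i + len(words)]]
        if not sensitive:
            surfaces = [s.lower() for s in surfaces]
        if surfaces == words:
            spans.append((i, i + len(words)))
    return spans


def classify_note_brute(text, lexicon, window=5):
    """Return (positive, mentions) where each mention is a dict with term,
    token span, sentence, suppressed flag and reason."""
    tokens = _tokens(text)
    sentences = _sentence_ids(text, tokens)

    candidates = []
    for lex_index, term in enumerate(lexicon.include_terms):
        for start, end in _occurrences(tokens, term):
            candidates.append((start, end, lex_index, term))
    candidates.sort(key=lambda c: (-(c[1] - c[0]), c[2], c[0]))
    chosen = []
    for cand in candidates:
        if all(cand[1] <= c[0] or cand[0] >= c[1] for c in chosen):
            chosen.append(cand)
    chosen.sort(key=lambda c: c[0])

    mentions = [
        {
            "term": term,
            "token_start": start,
            "token_end": end,
            "char_start": tokens[start][1],
            "char_end": tokens[end - 1][2],
            "sentence_index": sentences[start],
            "suppressed": False,
            "reason": "none",
        }
        for start, end, _lex, term in chosen
    ]

    qualifier_spans = []
    for term in lexicon.qualifier_terms:
        for start, end in _occurrences(tokens, term, force_case_insensitive=True):
            qualifier_spans.append((start, end, term))
    for mention in mentions:
        for qstart, qend, term in sorted(qualifier_spans):
            if qend > mention["token_start"]:
                continue
            if sentences[qend - 1] != mention["sentence_index"]:
                continue
            if mention["token_start"] - qend < window:
                mention["suppressed"] = True
                mention["reason"] = f"qualifier:{term}"
                break

    for rule in lexicon.exclusion_rules:
        if not _occurrences(tokens, rule.partner_phrase, force_case_insensitive=True):
            continue
        for mention in mentions:
            if not mention["suppressed"] and mention["term"] == rule.trigger_term:
                mention["suppressed"] = True
                mention["reason"] = f"exclusion:{rule.rule_id}"

    positive = any(not m["suppressed"] for m in mentions)
    return positive, mentions
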