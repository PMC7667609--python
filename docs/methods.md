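# Methods

## The screening model

`dicscreen` implements a deterministic, rule-based screen for disseminated
intravascular coagulopathy (DIC) over two evidence streams restricted to
the ICU stay window (inclusive at both ends):

- **Note search.** Notes are tokenized into maximal alphanumeric runs;
  sentence boundaries are `.`, `!`, `?` and newline, with runs of boundary
  characters counting once. Include terms are matched whole-word across
  consecutive tokens; multi-word terms case-insensitively, the acronym
  *DIC* case-sensitively as an all-caps standalone token (lowercase "dic"
  inside words or unrelated abbreviations would destroy specificity).
  Overlapping matches resolve longest-first, ties by lexicon order, so a
  phrase is never double counted. Two suppression passes follow:
  qualifiers, then co-occurrence exclusions. A note is positive iff a
  mention survives both.
- **Code search.** A patient is code-positive iff a code event matching
  the configured set (exact code or `*` prefix pattern, per code system)
  is timestamped inside a stay. Defaults are ICD-9-CM 286.6 and ICD-10-CM
  D65, the conventional DIC codes for a 2007–2018 ICU span; institutions
  that coded differently should override `code_set` in the YAML config.
- **Combination.** `notes_only`, `codes_only`, or `notes_or_codes`. The
  combined screen defaults to logical OR (the conventional broadened-screen
  reading); AND is available via `combine: and` for sensitivity analyses.

Assumptions: one patient's notes are independent evidence (any positive
note suffices); note timestamps and stay intervals share a clock (naive
timestamps are taken as UTC); identifiers are opaque and never parsed.

## Suppression semantics

The qualifier pass implements pre-negation in the NegEx tradition: a
mention is suppressed when a qualifier phrase (*no*, *negative*,
*history*, *ruled out*) occurs in the **same sentence** with its last
token among the `qualifier_window` tokens immediately preceding the
mention's first token. The window defaults to 5 tokens ("no evidence of
acute DIC" suppresses; a qualifier six tokens upstream does not) and is
configurable; window 0 disables the pass. Post-negation ("DIC: negative")
is deliberately not suppressed by default — the supported qualifiers are
all pre-modifiers — and would be a config extension.

The exclusion pass scopes the partner phrase to the **whole note**
(whole-word, case-insensitive): "DIC panel" names a lab order and "DIC vs
HIT" a differential wherever the words fall, and note scope is the
conservative reading that maximizes specificity. A rule suppresses only
mentions of its own trigger term: a note reading "consumptive
coagulopathy; DIC panel pending" stays positive through the surviving
coagulopathy mention. When several rules fire, the first in lexicon order
names the suppression reason. Suppression never deletes: every mention is
retained with its status and reason, so patient-level predictions and the
disagreement report can show exactly why a call was made.

## Evaluation

Predictions are compared with per-patient gold labels in a 2×2 table;
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP). 95% confidence
intervals use the Wilson score method (well-behaved at the n≈25 cohort
sizes this design uses; computed via statsmodels, with the interval
clamped to contain the point estimate against floating-point dust at 0 and
1). A metric with a zero denominator is reported as undefined — silently
coercing it to 0 or 1 would corrupt strategy comparisons.

`assemble_cohort` mirrors the study design: sample `n_meeting`
strategy-positive and `n_not` strategy-negative patients (default 25/25)
uniformly without replacement, deterministically per seed.
`compare_strategies` evaluates every strategy on **one shared cohort**,
assembled under the first strategy in the list; orderings such as
sensitivity(OR) ≥ sensitivity(notes) are only meaningful on a fixed
cohort, which is why the package never asserts them across separately
drawn cohorts.

## The synthetic corpus

The generator emulates the statistical structure the screen must
discriminate, not clinical language. Each patient has one ICU stay and
1–5 short templated notes; a latent DIC status provides the gold label
(standing in for manual chart review — laboratory values such as D-dimer,
fibrinogen, PT, APTT and platelet count are out of scope and noted as an
extension point). Defaults, chosen for test coverage and configurable:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 50 | cohort size (25/25 at the default prevalence) |
| `prevalence` | 0.5 | case fraction; hit exactly when `prevalence·n` is integral |
| `p_affirm_mention_if_case` | 0.95 | case has an affirmative-mention note (misses create FNs) |
| `p_negated_mention_if_control` | 0.2 | control has a qualifier-negated note |
| `p_confounder_note` | 0.1 each | control note per confounder class (panel, profile, HIT, fibrinolysis±liver disease/cirrhosis) |
| `p_code_if_case` / `p_code_if_control` | 0.6 / 0.02 | DIC code event inside the stay |
| `p_note_outside_stay` | 0.05 | note timestamped before admission (invisible to the screen) |

Every note's sentences are tagged with the template class that produced
them, and templates are constructed to be unambiguous under the engine's
documented scoping defaults (qualifiers within the 5-token window, exactly
one include term per payload, filler free of all lexicon/partner words).
`expected_oracle_labels` therefore derives the correct engine output from
provenance alone, giving an exact end-to-end oracle for any seed.

What passing these tests does **not** show: robustness to real clinical
prose — misspellings, section headers, templated boilerplate, post-negation,
hypothetical phrasing, copy-forward — none of which the generator emits.
The synthetic accuracy numbers characterize the pipeline's internal
consistency, not expected field performance on EMR data.

## Numerical and design choices

- Everything is deterministic given the seed: `random.Random(seed)` drives
  simulation and cohort sampling; re-running any command byte-reproduces
  its outputs, and the effective config is echoed into each output
  directory.
- Tokenization is fixed and documented (no stemming, no spelling
  correction): the method is a literal term search, and a mutable
  normalization layer would make the suppression semantics unauditable.
- Degenerate inputs: empty text yields a negative prediction with zero
  mentions; a patient without an ICU stay is an unusable record and raises
  rather than silently screening negative; missing gold labels fail the
  evaluation listing the offending patient ids.
- Test and script problem sizes (50–200 patients, 1,000 oracle notes, 20
  ordering seeds, exhaustive 0–30 metric margins) were chosen to exercise
  every rule and boundary while keeping the suite fast to iterate on.

## Known limitations

- The suppression scopes (sentence + 5-token pre-window; note-scope
  partners) are one defensible computable reading of a qualitative rule
  description; other sites' implementations may differ, so both are
  exposed in config rather than hard-coded.
- The default ICD code set is an assumption, not an institutional fact.
- The evaluation models a single reviewer gold standard; inter-reviewer
  disagreement and adjudication are reduced to the disagreement report.
- English-only, ASCII-oriented matching; no ontology mapping (UMLS) or
  general clinical NLP.
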