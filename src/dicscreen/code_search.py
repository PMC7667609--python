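"""The diagnosis-code strategy: flag a patient when a DIC ICD code event
falls inside an ICU stay window (inclusive at both ends).

The default code set uses the conventional DIC codes — ICD-9-CM 286.6
("Defibrination syndrome") and ICD-10-CM D65 — and is fully overridable.
A trailing ``*`` in a pattern matches any code with that prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_model import CodeEvent, PatientRecord, CODE_SYSTEMS


@dataclass(frozen=True)
class CodeSet:
    name: str
    codes: tuple[tuple[str, str], ...]  # (code_system, pattern)

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError("code set must be non-empty")
        normalized = []
        for system, pattern in self.codes:
            if system not in CODE_SYSTEMS:
                raise ValueError(f"code_system {system!r} not one of {CODE_SYSTEMS}")
            if not pattern:
                raise ValueError("empty code pattern")
            normalized.append((system, pattern.upper()))
        object.__setattr__(self, "codes", tuple(normalized))

    def matches(self, event: CodeEvent) -> bool:
        code = event.code.upper()
        for system, pattern in self.codes:
            if system != event.code_system:
                continue
            if pattern.endswith("*"):
                if code.startswith(pattern[:-1]):
                    return True
            elif code == pattern:
                return True
        return False


DEFAULT_CODE_SET = CodeSet(
    "dic_default",
    (("ICD9CM", "286.6"), ("ICD10CM", "D65")),
)


def match_codes(
    record: PatientRecord, code_set: CodeSet = DEFAULT_CODE_SET
) -> tuple[bool, list[CodeEvent]]:
    """True iff some code event matches the set and falls within a stay.

    Returns the matching events as evidence. A record with no stays is
    unusable for the ICU-window phenotype and raises ``ValueError``.
    """
    if not record.stays:
        raise ValueError(
            f"patient {record.patient_id!r} has no ICU stays; record unusable"
        )
    hits = [
        event
        for event in record.codes
        if code_set.matches(event)
        and any(
            stay.admit_ts <= event.timestamp <= stay.discharge_ts
            for stay in record.stays
        )
    ]
    return bool(hits), hits
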