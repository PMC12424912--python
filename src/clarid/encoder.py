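"""Identifier construction.

Two formats are produced from the same validated record:

* **human** — verbose, hyphen-delimited.  Biosamples carry nine mandatory
  fields (project, species, zero-padded subject id, tissue, sample type,
  assay, ICD-10 condition, timepoint, duration) plus optional batch and
  replicate tokens; subjects carry six (study, subject id, type, condition,
  sex, age group).
* **stub** — compact and delimiter-free.  Vocabulary components contribute
  fixed-width stub codes, the subject id is Base62-encoded to 3 characters,
  the condition becomes a 5-character token derived from its rank in the
  ICD-10 table, and the duration drops its leading "P".

Durations follow a restricted ISO 8601 grammar ("P" + count + unit, at most
3 characters, e.g. P1W = one week) with "P0N" as the not-available sentinel.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from .codebook import Codebook, ICD10Table, condition_rank, resolve_term
from .errors import ConfigurationError, DurationFormatError, RangeError, VocabularyError
from .layout import (
    BASE62_ALPHABET,
    BASE62_INDEX,
    BATCH_PREFIX,
    CONDITION_RANK_WIDTH,
    CONDITION_STUB_SUFFIX,
    OPTIONAL_DIGITS,
    REPLICATE_PREFIX,
    SUBJECT_ID_HUMAN_WIDTH,
    SUBJECT_ID_MAX,
)

__all__ = [
    "BiosampleRecord",
    "SubjectRecord",
    "base62_encode",
    "base62_decode",
    "format_subject_id_human",
    "validate_duration",
    "check_duration",
    "encode_condition_stub",
    "encode_biosample",
    "encode_subject",
    "sanitize_study",
]

_DURATION_RE = re.compile(r"^P(?:[0-9][DWMY]|0N)$")


@dataclass(frozen=True)
class BiosampleRecord:
    """Structured biosample metadata, the input and output of the codec."""

    project: str
    species: str
    subject_id: int
    tissue: str
    sample_type: str
    assay: str
    condition: str
    timepoint: str
    duration: str
    batch: int | None = None
    replicate: int | None = None


@dataclass(frozen=True)
class SubjectRecord:
    """Structured subject metadata."""

    study: str
    subject_id: int
    type: str
    condition: str
    sex: str
    age_group: str


def base62_encode(n: int, width: int) -> str:
    """Positional Base62 over 0-9, A-Z, a-z, zero-padded on the left."""
    if n < 0:
        raise RangeError(f"cannot Base62-encode negative value {n}")
    if n >= 62 ** width:
        raise RangeError(f"{n} does not fit in {width} Base62 characters")
    out = []
    for _ in range(width):
        n, r = divmod(n, 62)
        out.append(BASE62_ALPHABET[r])
    return "".join(reversed(out))


def base62_decode(token: str) -> int:
    value = 0
    if not token:
        raise VocabularyError("empty Base62 token")
    for ch in token:
        try:
            value = value * 62 + BASE62_INDEX[ch]
        except KeyError:
            raise VocabularyError(f"character {ch!r} outside the Base62 alphabet") from None
    return value


def format_subject_id_human(n: int) -> str:
    """Zero-padded 5-digit decimal subject id (1 -> "00001")."""
    if not isinstance(n, int) or isinstance(n, bool) or not 1 <= n <= SUBJECT_ID_MAX:
        raise RangeError(f"subject_id must be an integer in 1..{SUBJECT_ID_MAX}, got {n!r}")
    return f"{n:0{SUBJECT_ID_HUMAN_WIDTH}d}"


def validate_duration(s: str) -> str:
    """Check the restricted ISO 8601 duration grammar.

    Accepted: "P" + one digit + a unit among D/W/M/Y (e.g. P1W), or the
    sentinel "P0N" for "not available"; total length never exceeds 3.
    """
    if not isinstance(s, str):
        raise DurationFormatError(f"duration must be a string, got {type(s).__name__}")
    if len(s) > 3:
        raise DurationFormatError(f"duration {s!r} exceeds the 3-character maximum")
    if not _DURATION_RE.match(s):
        raise DurationFormatError(
            f"duration {s!r} is not P<digit><D|W|M|Y> or the sentinel P0N")
    return s


def check_duration(s: str, cb: Codebook | None = None) -> str:
    """Validate a duration against the codebook's rule (default grammar otherwise).

    Whatever the configured rule allows, the token must start with "P" (the
    stub format strips and restores that prefix) and stay within 3 characters.
    """
    rule = cb.regex_components.get("duration") if cb is not None else None
    if rule is None:
        return validate_duration(s)
    if not isinstance(s, str) or len(s) > 3 or not s.startswith("P"):
        raise DurationFormatError(
            f"duration {s!r} must start with 'P' and have at most 3 characters")
    if not rule.match(s):
        raise DurationFormatError(
            f"duration {s!r} does not match the codebook's duration rule")
    return s


def encode_condition_stub(code: str, table: ICD10Table) -> str:
    """5-character condition token: Base62 table rank (3) + reserved "01"."""
    rank = condition_rank(table, code)
    return base62_encode(rank, CONDITION_RANK_WIDTH) + CONDITION_STUB_SUFFIX


def sanitize_study(study: str) -> str:
    """Human-format study token: hyphens become underscores (hyphen is reserved)."""
    return study.replace("-", "_")


def _check_condition(record, table: ICD10Table) -> None:
    if record.condition not in table:
        raise VocabularyError(
            f"condition {record.condition!r} not in the ICD-10 lookup table")


def _check_optional(value, name: str):
    if value is None:
        return None
    if not isinstance(value, int) or isinstance(value, bool) or not 1 <= value <= 99:
        raise RangeError(f"{name} must be an integer in 1..99, got {value!r}")
    return value


def _optional_tokens(record: BiosampleRecord) -> list[str]:
    tokens = []
    batch = _check_optional(record.batch, "batch")
    replicate = _check_optional(record.replicate, "replicate")
    if batch is not None:
        tokens.append(f"{BATCH_PREFIX}{batch:0{OPTIONAL_DIGITS}d}")
    if replicate is not None:
        tokens.append(f"{REPLICATE_PREFIX}{replicate:0{OPTIONAL_DIGITS}d}")
    return tokens


def _stub_code(entry, entity: str, component: str) -> str:
    if entry.stub_code is None:
        raise ConfigurationError(
            f"{entity} {component} term {entry.term!r} has no stub_code in the "
            f"codebook; define one to use the stub format")
    return entry.stub_code


def encode_biosample(record: BiosampleRecord, cb: Codebook, table: ICD10Table,
                     fmt: str = "human") -> str:
    """Build a biosample identifier in the requested format."""
    entries = {
        component: resolve_term(cb, "biosample", component, getattr(record, component))
        for component in ("project", "species", "tissue", "sample_type", "assay", "timepoint")
    }
    _check_condition(record, table)
    duration = check_duration(record.duration, cb)
    optionals = _optional_tokens(record)

    if fmt == "human":
        tokens = [
            entries["project"].code,
            entries["species"].code,
            format_subject_id_human(record.subject_id),
            entries["tissue"].code,
            entries["sample_type"].code,
            entries["assay"].code,
            record.condition,
            entries["timepoint"].code,
            duration,
        ] + optionals
        return "-".join(tokens)
    if fmt == "stub":
        format_subject_id_human(record.subject_id)  # range check
        parts = [
            _stub_code(entries["project"], "biosample", "project"),
            _stub_code(entries["species"], "biosample", "species"),
            base62_encode(record.subject_id, 3),
            _stub_code(entries["tissue"], "biosample", "tissue"),
            _stub_code(entries["sample_type"], "biosample", "sample_type"),
            _stub_code(entries["assay"], "biosample", "assay"),
            encode_condition_stub(record.condition, table),
            _stub_code(entries["timepoint"], "biosample", "timepoint"),
            duration[1:],  # drop the leading "P"
        ] + optionals
        return "".join(parts)
    raise ConfigurationError(f"unknown format {fmt!r} (expected 'human' or 'stub')")


def encode_subject(record: SubjectRecord, cb: Codebook, table: ICD10Table,
                   fmt: str = "human") -> str:
    """Build a subject identifier in the requested format.

    The study component is free-form by default; when the codebook defines a
    ``subject.study`` vocabulary containing the term, its code/stub_code is
    used instead of the raw string.
    """
    if not record.study:
        raise VocabularyError("study must be non-empty")
    study_entry = None
    if cb.has_component("subject", "study") and record.study in cb.vocabulary("subject", "study"):
        study_entry = cb.vocabulary("subject", "study")[record.study]
    entries = {
        component: resolve_term(cb, "subject", component, getattr(record, component))
        for component in ("type", "sex", "age_group")
    }
    _check_condition(record, table)

    if fmt == "human":
        study = study_entry.code if study_entry else sanitize_study(record.study)
        tokens = [
            study,
            format_subject_id_human(record.subject_id),
            entries["type"].code,
            record.condition,
            entries["sex"].code,
            entries["age_group"].code,
        ]
        return "-".join(tokens)
    if fmt == "stub":
        format_subject_id_human(record.subject_id)  # range check
        prefix = record.study
        if study_entry is not None and study_entry.stub_code is not None:
            prefix = study_entry.stub_code
        parts = [
            prefix,
            base62_encode(record.subject_id, 3),
            _stub_code(entries["type"], "subject", "type"),
            encode_condition_stub(record.condition, table),
            _stub_code(entries["sex"], "subject", "sex"),
            _stub_code(entries["age_group"], "subject", "age_group"),
        ]
        return "".join(parts)
    raise ConfigurationError(f"unknown format {fmt!r} (expected 'human' or 'stub')")


def canonicalize(record):
    """Canonical form used for round-trip equality: study hyphens sanitized."""
    if isinstance(record, SubjectRecord):
        return replace(record, study=sanitize_study(record.study))
    return record
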