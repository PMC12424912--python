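"""Identifier parsing back into validated records.

Human-format identifiers are split on hyphens: the subject parse is
right-anchored (the last five tokens are fixed, everything before them is the
study name, which may itself contain hyphens); the biosample parse is
left-anchored with trailing optional tokens recognized by shape ("B" or "R"
plus two digits).

Stub identifiers carry no delimiters, so parsing relies on the fixed-width
layout.  The only variable-length elements are the leading project/study
token and the trailing duration payload; the project is recovered by trying
every project stub code that prefixes the identifier and keeping the unique
one whose remainder parses completely.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .codebook import (
    Codebook,
    ICD10Table,
    rank_to_condition,
    reverse_lookup,
)
from .encoder import (
    BiosampleRecord,
    SubjectRecord,
    base62_decode,
    check_duration,
)
from .errors import (
    AmbiguityError,
    ClaridError,
    ConfigurationError,
    RangeError,
    StructureError,
    VocabularyError,
)
from .layout import (
    BIOSAMPLE_STUB_FIXED,
    BIOSAMPLE_STUB_SLICES,
    CONDITION_RANK_WIDTH,
    CONDITION_STUB_SUFFIX,
    SUBJECT_ID_MAX,
    SUBJECT_STUB_SLICES,
    SUBJECT_STUB_TAIL,
)

__all__ = [
    "DecodedRecord",
    "decode_human",
    "decode_stub",
    "decode",
    "strip_optional_suffixes",
    "resolve_project_prefix",
    "attach_condition_name",
]

_OPTIONAL_RE = {"batch": re.compile(r"^B([0-9]{2})$"),
                "replicate": re.compile(r"^R([0-9]{2})$")}
_SUBJECT_ID_RE = re.compile(r"^[0-9]{5}$")


@dataclass(frozen=True)
class DecodedRecord:
    """A parsed identifier: the record plus provenance and optional condition name."""

    record: BiosampleRecord | SubjectRecord
    source_format: str
    condition_name: str | None = None


def _parse_subject_id_human(token: str) -> int:
    if not _SUBJECT_ID_RE.match(token):
        raise StructureError(f"subject_id token {token!r} is not 5 zero-padded digits")
    value = int(token)
    if value < 1:
        raise RangeError(f"subject_id must be positive, got {token!r}")
    return value


def _check_condition_human(token: str, cb: Codebook, table: ICD10Table) -> str:
    if not cb.rule("condition").match(token):
        raise StructureError(f"condition token {token!r} is not an ICD-10 code or NA")
    if token not in table:
        raise VocabularyError(f"condition {token!r} not in the ICD-10 lookup table")
    return token


def decode_human(identifier: str, entity: str, cb: Codebook, table: ICD10Table,
                 with_condition_name: bool = False) -> DecodedRecord:
    """Parse a hyphen-delimited identifier into a validated record."""
    identifier = identifier.strip()
    if not identifier:
        raise StructureError("empty identifier")
    tokens = identifier.split("-")
    if entity == "subject":
        if len(tokens) < 6:
            raise StructureError(
                f"subject identifier needs 6 hyphen-separated fields, got {len(tokens)}")
        study_tokens, tail = tokens[:-5], tokens[-5:]
        study = "-".join(study_tokens)
        if not study:
            raise StructureError("empty study component")
        if cb.has_component("subject", "study") and study in cb.code_index("subject", "study"):
            study = cb.code_index("subject", "study")[study]
        record = SubjectRecord(
            study=study,
            subject_id=_parse_subject_id_human(tail[0]),
            type=reverse_lookup(cb, "subject", "type", tail[1], "human"),
            condition=_check_condition_human(tail[2], cb, table),
            sex=reverse_lookup(cb, "subject", "sex", tail[3], "human"),
            age_group=reverse_lookup(cb, "subject", "age_group", tail[4], "human"),
        )
    elif entity == "biosample":
        batch = replicate = None
        if tokens and _OPTIONAL_RE["replicate"].match(tokens[-1]):
            replicate = int(tokens.pop()[1:])
        if tokens and _OPTIONAL_RE["batch"].match(tokens[-1]):
            batch = int(tokens.pop()[1:])
        if len(tokens) != 9:
            raise StructureError(
                f"biosample identifier needs 9 mandatory fields "
                f"(plus optional B##/R##), got {len(tokens)}")
        record = BiosampleRecord(
            project=reverse_lookup(cb, "biosample", "project", tokens[0], "human"),
            species=reverse_lookup(cb, "biosample", "species", tokens[1], "human"),
            subject_id=_parse_subject_id_human(tokens[2]),
            tissue=reverse_lookup(cb, "biosample", "tissue", tokens[3], "human"),
            sample_type=reverse_lookup(cb, "biosample", "sample_type", tokens[4], "human"),
            assay=reverse_lookup(cb, "biosample", "assay", tokens[5], "human"),
            condition=_check_condition_human(tokens[6], cb, table),
            timepoint=reverse_lookup(cb, "biosample", "timepoint", tokens[7], "human"),
            duration=check_duration(tokens[8], cb),
            batch=batch,
            replicate=replicate,
        )
    else:
        raise ConfigurationError(f"unknown entity {entity!r}")
    decoded = DecodedRecord(record, "human")
    return attach_condition_name(decoded, table) if with_condition_name else decoded


def strip_optional_suffixes(stub: str) -> tuple[str, int | None, int | None]:
    """Greedily remove, from the right, a replicate token then a batch token."""
    batch = replicate = None
    if len(stub) >= 3 and _OPTIONAL_RE["replicate"].match(stub[-3:]):
        replicate = int(stub[-2:])
        stub = stub[:-3]
    if len(stub) >= 3 and _OPTIONAL_RE["batch"].match(stub[-3:]):
        batch = int(stub[-2:])
        stub = stub[:-3]
    return stub, batch, replicate


def _decode_condition_stub(token: str, table: ICD10Table) -> str:
    rank_token, suffix = token[:CONDITION_RANK_WIDTH], token[CONDITION_RANK_WIDTH:]
    if suffix != CONDITION_STUB_SUFFIX:
        raise StructureError(
            f"condition stub {token!r} lacks the reserved {CONDITION_STUB_SUFFIX!r} suffix")
    code, _ = rank_to_condition(table, base62_decode(rank_token))
    return code


def _decode_subject_id_stub(token: str) -> int:
    value = base62_decode(token)
    if not 1 <= value <= SUBJECT_ID_MAX:
        raise RangeError(f"stub subject_id {token!r} decodes to {value}, outside 1..{SUBJECT_ID_MAX}")
    return value


def _parse_biosample_core(remainder: str, cb: Codebook, table: ICD10Table) -> dict:
    """Parse everything after the project stub under the fixed-width layout."""
    if not BIOSAMPLE_STUB_FIXED + 1 <= len(remainder) <= BIOSAMPLE_STUB_FIXED + 2:
        raise StructureError(
            f"stub core remainder has length {len(remainder)}, expected "
            f"{BIOSAMPLE_STUB_FIXED + 1}-{BIOSAMPLE_STUB_FIXED + 2}")
    fields: dict = {}
    pos = 0
    for component, width in BIOSAMPLE_STUB_SLICES:
        token = remainder[pos:pos + width]
        pos += width
        if component == "subject_id":
            fields[component] = _decode_subject_id_stub(token)
        elif component == "condition":
            fields[component] = _decode_condition_stub(token, table)
        else:
            fields[component] = reverse_lookup(cb, "biosample", component, token, "stub")
    fields["duration"] = check_duration("P" + remainder[pos:], cb)
    return fields


def resolve_project_prefix(core: str, cb: Codebook,
                           table: ICD10Table | None = None) -> tuple[str, str]:
    """Find the unique project whose stub code prefixes *core* with a full parse.

    Project stub codes are variable-length, so the prefix alone may be
    ambiguous; a candidate only counts when the remainder parses completely
    under the fixed-width layout.  Zero candidates and multiple full parses
    raise distinct errors.
    """
    if table is None:
        from .codebook import load_icd10
        table = load_icd10()
    term, fields = _resolve_biosample_core(core, cb, table)
    stub = cb.vocabulary("biosample", "project")[term].stub_code
    return term, core[len(stub):]


def decode_stub(identifier: str, entity: str, cb: Codebook, table: ICD10Table,
                with_condition_name: bool = False) -> DecodedRecord:
    """Parse a delimiter-free stub identifier into a validated record."""
    identifier = identifier.strip()
    if not identifier:
        raise StructureError("empty identifier")
    if entity == "subject":
        if len(identifier) <= SUBJECT_STUB_TAIL:
            raise StructureError(
                f"subject stub must be longer than {SUBJECT_STUB_TAIL} characters "
                "(study prefix + fixed tail)")
        prefix, tail = identifier[:-SUBJECT_STUB_TAIL], identifier[-SUBJECT_STUB_TAIL:]
        fields: dict = {}
        pos = 0
        for component, width in SUBJECT_STUB_SLICES:
            token = tail[pos:pos + width]
            pos += width
            if component == "subject_id":
                fields[component] = _decode_subject_id_stub(token)
            elif component == "condition":
                fields[component] = _decode_condition_stub(token, table)
            else:
                fields[component] = reverse_lookup(cb, "subject", component, token, "stub")
        study = prefix
        if cb.has_component("subject", "study") and prefix in cb.stub_index("subject", "study"):
            study = cb.stub_index("subject", "study")[prefix]
        record: SubjectRecord | BiosampleRecord = SubjectRecord(study=study, **fields)
    elif entity == "biosample":
        core, batch, replicate = strip_optional_suffixes(identifier)
        try:
            project, fields = _resolve_biosample_core(core, cb, table)
        except ClaridError:
            # Parse guard: if suffix stripping broke the layout but the
            # unstripped string parses, the unstripped parse wins.
            if batch is None and replicate is None:
                raise
            project, fields = _resolve_biosample_core(identifier, cb, table)
            batch = replicate = None
        record = BiosampleRecord(project=project, batch=batch, replicate=replicate, **fields)
    else:
        raise ConfigurationError(f"unknown entity {entity!r}")
    decoded = DecodedRecord(record, "stub")
    return attach_condition_name(decoded, table) if with_condition_name else decoded


def _resolve_biosample_core(core: str, cb: Codebook, table: ICD10Table) -> tuple[str, dict]:
    if not core:
        raise StructureError("empty stub identifier")
    candidates = [
        (term, entry.stub_code)
        for term, entry in cb.vocabulary("biosample", "project").items()
        if entry.stub_code and core.startswith(entry.stub_code)
    ]
    if not candidates:
        raise StructureError("no project stub code matches the identifier prefix")
    parses = []
    for term, stub in candidates:
        try:
            parses.append((term, _parse_biosample_core(core[len(stub):], cb, table)))
        except ClaridError:
            continue
    if not parses:
        raise StructureError(
            "no project stub code yields a complete parse of the identifier")
    if len(parses) > 1:
        names = ", ".join(sorted(term for term, _ in parses))
        raise AmbiguityError(
            f"ambiguous stub: projects {names} all parse; redefine project stub_codes")
    return parses[0]


def decode(identifier: str, entity: str, cb: Codebook, table: ICD10Table,
           fmt: str = "human", with_condition_name: bool = False) -> DecodedRecord:
    """Dispatch to :func:`decode_human` or :func:`decode_stub`."""
    if fmt == "human":
        return decode_human(identifier, entity, cb, table, with_condition_name)
    if fmt == "stub":
        return decode_stub(identifier, entity, cb, table, with_condition_name)
    raise ConfigurationError(f"unknown format {fmt!r} (expected 'human' or 'stub')")


def attach_condition_name(decoded: DecodedRecord, table: ICD10Table) -> DecodedRecord:
    """Attach the display name of the record's ICD-10 condition.

    The "NA" sentinel maps to the documented placeholder "not available".
    """
    code = decoded.record.condition
    if code not in table:
        raise VocabularyError(f"condition {code!r} not in the ICD-10 lookup table")
    return DecodedRecord(decoded.record, decoded.source_format, table.names[code])
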