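"""Codebook loading, validation and lookup.

The codebook is a YAML document organized around the ``biosample`` and
``subject`` entities.  Each component (project, species, tissue, ...) maps
vocabulary terms to a long-form ``code`` used in the human-readable format and
a compact ``stub_code`` used in the delimiter-free stub format; ``label`` and
``id`` (an ontology CURIE such as ``UBERON:0002107``) are reference-only.
Rule-based components (condition, subject_id, duration, batch, replicate) are
defined by regular expressions under a ``rules`` section because enumerating
their values would be impractical.

Clinical conditions are not part of the codebook: they are ICD-10 codes,
validated and name-translated through a bundled JSON lookup table
(:class:`ICD10Table`), whose rank order also drives the compact condition
encoding.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml

from . import _schema
from .errors import CodebookError, ConditionLookupError, ConfigurationError, VocabularyError
from .layout import STUB_WIDTHS

__all__ = [
    "CodebookEntry",
    "Codebook",
    "ICD10Table",
    "Finding",
    "ValidationReport",
    "load_codebook",
    "validate_codebook",
    "resolve_term",
    "reverse_lookup",
    "condition_rank",
    "rank_to_condition",
    "load_icd10",
    "bundled_codebook_path",
    "bundled_schema_path",
    "bundled_icd10_path",
]

#: Vocabulary components that must be present per entity.
REQUIRED_COMPONENTS = {
    "biosample": ("project", "species", "tissue", "sample_type", "assay", "timepoint"),
    "subject": ("type", "sex", "age_group"),
}

#: Free-text components: variable-length stub codes, stub_code optional.
FREE_COMPONENTS = {("biosample", "project"), ("subject", "study")}

#: Rule-based (regex-defined) components and their default patterns.
DEFAULT_RULES = {
    "condition": r"^(?:[A-Z][0-9]{2}(?:\.[0-9]{1,2})?|NA)$",
    "duration": r"^P(?:[0-9][DWMY]|0N)$",
    "subject_id": r"^[0-9]{1,5}$",
    "batch": r"^[0-9]{1,2}$",
    "replicate": r"^[0-9]{1,2}$",
}

_CURIE_RE = re.compile(r"^[A-Za-z0-9_.]+:[A-Za-z0-9_.]+$")
_CODE_RE = re.compile(r"^[A-Za-z0-9_.]+$")
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9]{1,2})?$")
_ENTRY_KEYS = {"code", "stub_code", "label", "id", "tax_code"}


@dataclass(frozen=True)
class CodebookEntry:
    """One controlled vocabulary term."""

    term: str
    code: str
    stub_code: str | None = None
    label: str | None = None
    id: str | None = None
    tax_code: str | None = None


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    path: str
    message: str


@dataclass
class ValidationReport:
    findings: list[Finding] = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return not any(f.severity == "error" for f in self.findings)

    def errors(self) -> list[Finding]:
        return [f for f in self.findings if f.severity == "error"]


class Codebook:
    """In-memory codebook with forward and reverse indexes."""

    def __init__(self, entities: dict[str, dict[str, dict[str, CodebookEntry]]],
                 regex_components: dict[str, re.Pattern],
                 warnings: Iterable[Finding] = ()) -> None:
        self.entities = entities
        self.regex_components = regex_components
        self.warnings = list(warnings)
        self._by_code: dict[tuple[str, str], dict[str, str]] = {}
        self._by_stub: dict[tuple[str, str], dict[str, str]] = {}
        for entity, components in entities.items():
            for component, terms in components.items():
                codes, stubs = {}, {}
                for term, entry in terms.items():
                    codes[entry.code] = term
                    if entry.stub_code is not None:
                        stubs[entry.stub_code] = term
                self._by_code[(entity, component)] = codes
                self._by_stub[(entity, component)] = stubs

    def vocabulary(self, entity: str, component: str) -> dict[str, CodebookEntry]:
        try:
            return self.entities[entity][component]
        except KeyError:
            raise VocabularyError(
                f"no vocabulary for component {entity}.{component}") from None

    def has_component(self, entity: str, component: str) -> bool:
        return component in self.entities.get(entity, {})

    def rule(self, component: str) -> re.Pattern:
        return self.regex_components[component]

    def code_index(self, entity: str, component: str) -> dict[str, str]:
        return self._by_code[(entity, component)]

    def stub_index(self, entity: str, component: str) -> dict[str, str]:
        return self._by_stub[(entity, component)]


class ICD10Table:
    """Ordered ICD-10 code -> name lookup.

    Rank 0 is reserved for the "NA" sentinel; the remaining entries are sorted
    lexicographically by code, which makes the rank of a code stable for a
    given table file and lets the stub format encode conditions as Base62
    ranks.
    """

    def __init__(self, entries: list[tuple[str, str]]) -> None:
        if not entries or entries[0][0] != "NA":
            raise CodebookError('ICD-10 table must start with the "NA" sentinel')
        codes = [c for c, _ in entries]
        if len(set(codes)) != len(codes):
            raise CodebookError("ICD-10 table contains duplicate codes")
        body = codes[1:]
        if body != sorted(body):
            raise CodebookError("ICD-10 table entries must be sorted lexicographically by code")
        for code in body:
            if not _ICD10_RE.match(code):
                raise CodebookError(f"malformed ICD-10 code in table: {code!r}")
        self.entries = entries
        self.rank = {code: i for i, (code, _) in enumerate(entries)}
        self.names = dict(entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: str) -> bool:
        return code in self.rank


def bundled_codebook_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/codebook.yaml")))


def bundled_schema_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/codebook.schema.json")))


def bundled_icd10_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/icd10.json")))


def _coerce(value) -> str | None:
    if value is None:
        return None
    return str(value).strip()


def _iter_clarid_findings(doc) -> Iterable[Finding]:
    """ClarID-specific structural checks beyond the JSON Schema."""
    if not isinstance(doc, dict) or not ({"biosample", "subject"} & set(doc)):
        yield Finding("error", "$", "missing entity sections (biosample/subject)")
        return
    for entity in ("biosample", "subject"):
        section = doc.get(entity)
        if section is None:
            yield Finding("error", entity, f"missing entity section {entity!r}")
            continue
        if not isinstance(section, dict):
            yield Finding("error", entity, "entity section must be a mapping")
            continue
        for component in REQUIRED_COMPONENTS[entity]:
            if component not in section:
                yield Finding("error", f"{entity}.{component}",
                              f"missing required component {component!r}")
        for component, terms in section.items():
            cpath = f"{entity}.{component}"
            if not isinstance(terms, dict) or not terms:
                yield Finding("error", cpath, "component must map terms to entries")
                continue
            width = STUB_WIDTHS.get(entity, {}).get(component)
            free = (entity, component) in FREE_COMPONENTS
            if width is None and not free:
                yield Finding("warning", cpath, "component unknown to the identifier layout")
            seen_codes: dict[str, str] = {}
            seen_stubs: dict[str, str] = {}
            for term, entry in terms.items():
                tpath = f"{cpath}.{term}"
                if not isinstance(entry, dict):
                    yield Finding("error", tpath, "entry must be a mapping")
                    continue
                for key in set(entry) - _ENTRY_KEYS:
                    yield Finding("warning", f"{tpath}.{key}", f"unknown key {key!r}")
                code = _coerce(entry.get("code"))
                if not code:
                    yield Finding("error", tpath, "missing required key 'code'")
                else:
                    if "-" in code:
                        yield Finding("error", f"{tpath}.code",
                                      f"code {code!r} contains a hyphen (reserved delimiter)")
                    elif not _CODE_RE.match(code):
                        yield Finding("error", f"{tpath}.code",
                                      f"code {code!r} contains characters outside [A-Za-z0-9_.]")
                    if code in seen_codes:
                        yield Finding("error", cpath,
                                      f"duplicate code {code!r} (terms {seen_codes[code]!r}, {term!r})")
                    seen_codes.setdefault(code, term)
                stub = _coerce(entry.get("stub_code"))
                if stub is None:
                    if not free:
                        yield Finding("error", tpath, "missing required key 'stub_code'")
                else:
                    if not stub:
                        yield Finding("error", f"{tpath}.stub_code", "stub_code is empty")
                    elif width is not None and len(stub) != width:
                        yield Finding("error", f"{tpath}.stub_code",
                                      f"stub_code {stub!r} has width {len(stub)}, expected {width}")
                    if stub in seen_stubs:
                        yield Finding("error", cpath,
                                      f"duplicate stub_code {stub!r} "
                                      f"(terms {seen_stubs[stub]!r}, {term!r})")
                    seen_stubs.setdefault(stub, term)
                curie = _coerce(entry.get("id"))
                if curie and not _CURIE_RE.match(curie):
                    yield Finding("error", f"{tpath}.id",
                                  f"id {curie!r} is not a CURIE (prefix:reference)")
    rules = doc.get("rules", {})
    if rules is not None:
        if not isinstance(rules, dict):
            yield Finding("error", "rules", "rules section must be a mapping")
        else:
            for name, pattern in rules.items():
                try:
                    re.compile(str(pattern))
                except re.error as exc:
                    yield Finding("error", f"rules.{name}", f"invalid regex: {exc}")


def _parse_yaml(path) -> dict:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise ConfigurationError(f"cannot read codebook {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CodebookError(f"YAML syntax error in {path}: {exc}") from exc
    return doc


def load_codebook(path=None) -> Codebook:
    """Load and structurally validate a codebook YAML file.

    With no argument, loads the bundled example codebook.  Raises
    :class:`CodebookError` naming the offending path on any structural
    violation; unknown keys and components only produce warnings, kept on
    ``Codebook.warnings`` (the codebook is user-extensible by design).
    """
    path = bundled_codebook_path() if path is None else Path(path)
    doc = _parse_yaml(path)
    findings = list(_iter_clarid_findings(doc))
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        head = errors[0]
        raise CodebookError(
            f"invalid codebook {path}: {head.path}: {head.message}"
            + (f" (+{len(errors) - 1} more)" if len(errors) > 1 else ""))

    entities: dict[str, dict[str, dict[str, CodebookEntry]]] = {}
    for entity in ("biosample", "subject"):
        entities[entity] = {}
        for component, terms in doc[entity].items():
            table = {}
            for term, raw in terms.items():
                term = str(term)
                table[term] = CodebookEntry(
                    term=term,
                    code=_coerce(raw.get("code")),
                    stub_code=_coerce(raw.get("stub_code")),
                    label=_coerce(raw.get("label")),
                    id=_coerce(raw.get("id")),
                    tax_code=_coerce(raw.get("tax_code")),
                )
            entities[entity][component] = table
    rules = dict(DEFAULT_RULES)
    for name, pattern in (doc.get("rules") or {}).items():
        rules[str(name)] = str(pattern)
    compiled = {name: re.compile(pattern) for name, pattern in rules.items()}
    warnings = [f for f in findings if f.severity == "warning"]
    return Codebook(entities, compiled, warnings)


def validate_codebook(cb_path, schema_path=None) -> ValidationReport:
    """Validate a codebook file against a JSON Schema plus ClarID rules.

    Schema violations and ClarID-specific findings (duplicate codes or stub
    codes, wrong stub widths, hyphens in codes) are collected into one
    :class:`ValidationReport`; a malformed schema document raises
    :class:`ConfigurationError` instead of producing a report.
    """
    schema_path = bundled_schema_path() if schema_path is None else Path(schema_path)
    try:
        schema = json.loads(Path(schema_path).read_text(encoding="utf-8"))
    except OSError as exc:
        raise ConfigurationError(f"cannot read schema {schema_path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"schema {schema_path} is not valid JSON: {exc}") from exc
    _schema.check_schema_document(schema)

    doc = _parse_yaml(cb_path)
    report = ValidationReport()
    for path, message in _schema.iter_errors(doc, schema):
        report.findings.append(Finding("error", path, f"schema: {message}"))
    report.findings.extend(_iter_clarid_findings(doc))
    return report


def resolve_term(cb: Codebook, entity: str, component: str, term: str) -> CodebookEntry:
    """Exact, case-sensitive forward lookup of a vocabulary term."""
    vocab = cb.vocabulary(entity, component)
    try:
        return vocab[term]
    except KeyError:
        valid = ", ".join(sorted(vocab))
        raise VocabularyError(
            f"unknown {entity} {component} term {term!r}; valid terms: {valid}") from None


def reverse_lookup(cb: Codebook, entity: str, component: str, token: str,
                   fmt: str = "human") -> str:
    """Map a code (fmt="human") or stub_code (fmt="stub") back to its term."""
    index = cb.code_index(entity, component) if fmt == "human" \
        else cb.stub_index(entity, component)
    try:
        return index[token]
    except KeyError:
        raise VocabularyError(
            f"token {token!r} is not a known {fmt} code for {entity}.{component}") from None


def load_icd10(path=None) -> ICD10Table:
    """Load the ICD-10 lookup table (bundled mini table by default)."""
    path = bundled_icd10_path() if path is None else Path(path)
    try:
        raw = json.loads(Path(path).read_text(encoding="utf-8"))
    except OSError as exc:
        raise ConfigurationError(f"cannot read ICD-10 table {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise CodebookError(f"ICD-10 table {path} is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise CodebookError("ICD-10 table must be a JSON array of {code, name} objects")
    entries = []
    for item in raw:
        if not isinstance(item, dict) or "code" not in item or "name" not in item:
            raise CodebookError("each ICD-10 table entry needs 'code' and 'name'")
        entries.append((str(item["code"]), str(item["name"])))
    return ICD10Table(entries)


def condition_rank(table: ICD10Table, code: str) -> int:
    """0-based position of *code* in the table order; rank("NA") == 0."""
    try:
        return table.rank[code]
    except KeyError:
        raise ConditionLookupError(f"ICD-10 code {code!r} not in the lookup table") from None


def rank_to_condition(table: ICD10Table, rank: int) -> tuple[str, str]:
    """Inverse of :func:`condition_rank`: rank -> (code, name)."""
    if not 0 <= rank < len(table.entries):
        raise ConditionLookupError(
            f"condition rank {rank} outside table of size {len(table.entries)}")
    return table.entries[rank]
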