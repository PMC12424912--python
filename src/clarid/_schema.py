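"""Minimal JSON Schema (draft 2020-12 subset) validator.

Covers the keywords used by the shipped codebook schema and by typical
user-supplied variants: ``type``, ``properties``, ``patternProperties``,
``additionalProperties``, ``required``, ``minProperties``, ``pattern``,
``minLength``, ``maxLength``, ``enum``, ``items``, ``minItems`` and local
``$ref`` / ``$defs`` resolution.  Unknown keywords are ignored, as a full
validator would ignore unrecognized annotations.
"""

from __future__ import annotations

import re
from typing import Any, Iterator

from .errors import ConfigurationError

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}


def _resolve_ref(ref: str, root: dict) -> Any:
    if not ref.startswith("#"):
        raise ConfigurationError(f"only local $ref pointers are supported, got {ref!r}")
    node: Any = root
    for part in ref.lstrip("#/").split("/"):
        if not part:
            continue
        part = part.replace("~1", "/").replace("~0", "~")
        try:
            node = node[part]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"unresolvable $ref {ref!r}") from exc
    return node


def _check_type(instance: Any, expected: str | list[str]) -> bool:
    names = [expected] if isinstance(expected, str) else expected
    for name in names:
        py = _TYPES.get(name)
        if py is None:
            raise ConfigurationError(f"unsupported JSON Schema type {name!r}")
        # bool is a subclass of int in Python; keep the JSON distinction.
        if name in ("integer", "number") and isinstance(instance, bool):
            continue
        if isinstance(instance, py):
            return True
    return False


def iter_errors(instance: Any, schema: Any, root: dict | None = None,
                path: str = "$") -> Iterator[tuple[str, str]]:
    """Yield ``(json_path, message)`` pairs for every violation."""
    if schema is True or schema == {}:
        return
    if schema is False:
        yield path, "schema forbids this value"
        return
    if not isinstance(schema, dict):
        raise ConfigurationError("schema node must be an object or boolean")
    if root is None:
        root = schema

    if "$ref" in schema:
        yield from iter_errors(instance, _resolve_ref(schema["$ref"], root), root, path)
        return

    if "type" in schema and not _check_type(instance, schema["type"]):
        yield path, f"expected type {schema['type']}, got {type(instance).__name__}"
        return

    if "enum" in schema and instance not in schema["enum"]:
        yield path, f"value {instance!r} not one of {schema['enum']!r}"

    if isinstance(instance, str):
        if "minLength" in schema and len(instance) < schema["minLength"]:
            yield path, f"string shorter than minLength {schema['minLength']}"
        if "maxLength" in schema and len(instance) > schema["maxLength"]:
            yield path, f"string longer than maxLength {schema['maxLength']}"
        if "pattern" in schema and not re.search(schema["pattern"], instance):
            yield path, f"string {instance!r} does not match pattern {schema['pattern']!r}"

    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                yield path, f"missing required property {key!r}"
        if "minProperties" in schema and len(instance) < schema["minProperties"]:
            yield path, f"object has fewer than {schema['minProperties']} properties"
        props = schema.get("properties", {})
        patterns = schema.get("patternProperties", {})
        additional = schema.get("additionalProperties", True)
        for key, value in instance.items():
            child = f"{path}.{key}"
            matched = False
            if key in props:
                matched = True
                yield from iter_errors(value, props[key], root, child)
            for pat, sub in patterns.items():
                if re.search(pat, str(key)):
                    matched = True
                    yield from iter_errors(value, sub, root, child)
            if not matched and additional is not True:
                if additional is False:
                    yield child, "additional property not allowed"
                else:
                    yield from iter_errors(value, additional, root, child)

    if isinstance(instance, list):
        if "minItems" in schema and len(instance) < schema["minItems"]:
            yield path, f"array has fewer than {schema['minItems']} items"
        if "items" in schema:
            for i, item in enumerate(instance):
                yield from iter_errors(item, schema["items"], root, f"{path}[{i}]")


def check_schema_document(schema: Any) -> None:
    """Raise :class:`ConfigurationError` if *schema* is not usable."""
    if not isinstance(schema, (dict, bool)):
        raise ConfigurationError("JSON Schema document must be an object")
    # Walk once over an empty instance to surface malformed refs/patterns early.
    if isinstance(schema, dict):
        for pat_map in ("properties", "patternProperties", "$defs"):
            sub = schema.get(pat_map, {})
            if not isinstance(sub, dict):
                raise ConfigurationError(f"schema keyword {pat_map!r} must map to an object")
        for pat in schema.get("patternProperties", {}):
            try:
                re.compile(pat)
            except re.error as exc:
                raise ConfigurationError(f"invalid patternProperties regex {pat!r}: {exc}")
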