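"""Minimal JSON-schema checker for the analysis report.

Supports the subset of JSON Schema the shipped ``report_schema.json`` uses:
``type`` (string or list of strings), ``properties`` + ``required`` for
objects, ``items`` for arrays, and ``enum``.
"""

from __future__ import annotations

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "boolean": bool,
    "null": type(None),
}


class SchemaError(ValueError):
    pass


def _type_ok(value, typename: str) -> bool:
    if typename == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if typename == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    return isinstance(value, _TYPES[typename])


def validate(value, schema: dict, path: str = "$") -> None:
    """Raise :class:`SchemaError` if ``value`` does not satisfy ``schema``."""
    types = schema.get("type")
    if types is not None:
        allowed = [types] if isinstance(types, str) else types
        if not any(_type_ok(value, t) for t in allowed):
            raise SchemaError(
                f"{path}: expected type {allowed}, got {type(value).__name__}"
            )
    if "enum" in schema and value not in schema["enum"]:
        raise SchemaError(f"{path}: {value!r} not in enum {schema['enum']}")
    if isinstance(value, dict):
        for key in schema.get("required", []):
            if key not in value:
                raise SchemaError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in value:
                validate(value[key], sub, f"{path}.{key}")
    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            validate(item, schema["items"], f"{path}[{i}]")
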