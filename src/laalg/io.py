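"""Algebra JSON exchange format.

All CLI commands read and write this format.  Scalars cross the boundary as
exact strings/objects ("3/4", {"a": "-1/2", "b": "1/2"}, coefficient
lists) — never floats, which would silently break exactness.

Schema (informal)::

    {
      "format": "genetic-algebra/1",
      "field": {"kind": "rational"}
               | {"kind": "quadratic", "discriminant": 5}
               | {"kind": "finite", "p": 2, "k": 2, "modulus": [1, 1, 1]}
               | {"kind": "symbolic", "symbols": ["r", "s"]},
      "basis": ["a1", "a2", ...],
      "tensor": [[[scalar, ...], ...], ...],   # n x n x n, gamma[i][j][k]
      "provenance": {...}                      # constructor, parameters, seed
    }

The finite-field modulus and element coefficient lists are written with the
leading coefficient first.  Validation errors carry JSON-pointer-style
paths (``/tensor/0/1/2``).
"""

from __future__ import annotations

import json
from typing import Union

from .algebra import Algebra, StructureTensor
from .fields import Field, FieldError, field_from_json

__all__ = ["algebra_to_json", "algebra_from_json", "dump_algebra", "load_algebra",
           "FormatError", "FORMAT_TAG"]

FORMAT_TAG = "genetic-algebra/1"


class FormatError(ValueError):
    """A malformed algebra document; message includes a JSON-pointer path."""


def algebra_to_json(A: Algebra) -> dict:
    f = A.field
    return {
        "format": FORMAT_TAG,
        "field": f.spec_json(),
        "basis": list(A.basis_labels),
        "tensor": [
            [[f.raw_to_json(v) for v in row] for row in plane]
            for plane in A.tensor.entries
        ],
        "provenance": A.provenance,
    }


def algebra_from_json(doc: dict) -> Algebra:
    if not isinstance(doc, dict):
        raise FormatError(f"at /: expected an object, got {type(doc).__name__}")
    for key in ("field", "basis", "tensor"):
        if key not in doc:
            raise FormatError(f"at /: missing required key {key!r}")
    try:
        field = field_from_json(doc["field"])
    except FieldError as exc:
        raise FormatError(f"at /field: {exc}") from exc
    basis = doc["basis"]
    if not (isinstance(basis, list) and basis
            and all(isinstance(b, str) for b in basis)):
        raise FormatError("at /basis: expected a non-empty list of strings")
    n = len(basis)
    tensor_doc = doc["tensor"]
    if not (isinstance(tensor_doc, list) and len(tensor_doc) == n):
        raise FormatError(f"at /tensor: expected {n} planes, got "
                          f"{len(tensor_doc) if isinstance(tensor_doc, list) else type(tensor_doc).__name__}")
    entries = []
    for i, plane in enumerate(tensor_doc):
        if not (isinstance(plane, list) and len(plane) == n):
            raise FormatError(f"at /tensor/{i}: expected {n} rows")
        plane_out = []
        for j, row in enumerate(plane):
            if not (isinstance(row, list) and len(row) == n):
                raise FormatError(f"at /tensor/{i}/{j}: expected {n} scalars")
            row_out = []
            for k, scalar in enumerate(row):
                try:
                    row_out.append(field.raw_from_json(scalar))
                except (FieldError, ValueError) as exc:
                    raise FormatError(f"at /tensor/{i}/{j}/{k}: {exc}") from exc
            plane_out.append(row_out)
        entries.append(plane_out)
    provenance = doc.get("provenance", {})
    if not isinstance(provenance, dict):
        raise FormatError("at /provenance: expected an object")
    return Algebra(field, basis, StructureTensor(field, entries), provenance)


def dump_algebra(A: Algebra, path) -> None:
    with open(path, "w") as fh:
        json.dump(algebra_to_json(A), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_algebra(path) -> Algebra:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    return algebra_from_json(doc)
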