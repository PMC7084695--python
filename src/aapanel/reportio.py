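"""Structured-report serialization (JSON).

Reports carry every numeric field at full double precision for machine
round-trips, plus a rounded ``human_readable`` block for quick inspection.
Empty collections are written explicitly (an empty consensus subset is an
empty list under its key, never an absent key).
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Any

import numpy as np


def to_jsonable(obj: Any) -> Any:
    """Recursively convert reports/dataclasses/arrays to JSON-safe values."""
    if obj is None or isinstance(obj, (bool, int, str)):
        return obj
    if isinstance(obj, float):
        return None if math.isnan(obj) else obj
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return to_jsonable(obj.item())
    if isinstance(obj, np.ndarray):
        return [to_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"report_type": type(obj).__name__}
        for f in dataclasses.fields(obj):
            out[f.name] = to_jsonable(getattr(obj, f.name))
        if type(obj).__name__ == "LogitModel":
            named = {"intercept": float(obj.beta0)}
            named.update(
                (name, float(b)) for name, b in zip(obj.variable_names, obj.betas)
            )
            out["named_coefficients"] = named
        # computed properties worth persisting
        for prop in ("sensitivity", "specificity", "accuracy", "coefficients"):
            if hasattr(obj, prop) and prop not in out:
                try:
                    out[prop] = to_jsonable(getattr(obj, prop))
                except Exception:
                    pass
        return out
    if isinstance(obj, dict):
        return {_key(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [to_jsonable(v) for v in obj]
    return repr(obj)


def _key(k: Any) -> str:
    if isinstance(k, tuple):
        return "+".join(str(x) for x in k) if k else "(empty)"
    return str(k)


def _rounded(value: Any, ndigits: int = 3) -> Any:
    if isinstance(value, float):
        return round(value, ndigits)
    if isinstance(value, dict):
        return {k: _rounded(v, ndigits) for k, v in value.items()}
    if isinstance(value, list):
        return [_rounded(v, ndigits) for v in value]
    return value


def write_report(result: Any, path, **metadata) -> None:
    """Serialize a finished report object to JSON at ``path``.

    Extra keyword arguments (seed, config hash, ...) are stored under
    ``metadata``.  Floats are written at full precision; a rounded copy of
    the same content is included under ``human_readable``.
    """
    body = to_jsonable(result)
    doc = {
        "report": body,
        "human_readable": _rounded(body),
    }
    if metadata:
        doc["metadata"] = to_jsonable(metadata)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, allow_nan=False)
        fh.write("\n")


def read_report(path) -> dict:
    """Read back a report written by :func:`write_report` (full-precision part)."""
    with open(path) as fh:
        return json.load(fh)
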