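"""Assembly of the full three-step validation report.

Bundles the step-1 (relatedness), step-2 (performance) and step-3 (updating)
results, together with provenance (seeds, config hashes, package version),
into a versioned JSON-serializable structure that round-trips losslessly and
hashes deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from typing import Any, Mapping

import numpy as np

SCHEMA_VERSION = "1.0"

_MANDATORY = ("performance",)
_SECTIONS = ("relatedness", "performance", "updating")

__all__ = ["build_report", "serialize_report", "parse_report", "report_hash"]


def _plain(obj: Any) -> Any:
    """Recursively convert results (dataclasses, arrays) to JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def build_report(
    *,
    performance: Mapping | Any,
    relatedness: Mapping | Any = None,
    updating: Mapping | Any = None,
    provenance: Mapping | None = None,
) -> dict:
    """Assemble the validation report; at least step-2 results are required.

    Raises ``ValueError`` listing the missing mandatory sections.
    """
    sections = {"relatedness": relatedness, "performance": performance, "updating": updating}
    missing = [s for s in _MANDATORY if sections.get(s) is None]
    if missing:
        raise ValueError(f"missing mandatory report sections: {missing}")
    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": _plain(dict(provenance or {})),
    }
    for s in _SECTIONS:
        if sections[s] is not None:
            report[s] = _plain(sections[s])
    validate_report(report)
    return report


def validate_report(report: Mapping) -> None:
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("unknown or missing schema_version")
    missing = [s for s in _MANDATORY if s not in report]
    if missing:
        raise ValueError(f"missing mandatory report sections: {missing}")


def serialize_report(report: Mapping) -> str:
    return json.dumps(report, indent=2, sort_keys=True, allow_nan=False)


def parse_report(text: str) -> dict:
    report = json.loads(text)
    validate_report(report)
    return report


def report_hash(report: Mapping) -> str:
    """Content hash of the canonical serialization (determinism check)."""
    canon = json.dumps(report, sort_keys=True, separators=(",", ":"), allow_nan=False)
    return hashlib.sha256(canon.encode()).hexdigest()
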