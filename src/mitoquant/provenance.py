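"""Provenance logging for derived analysis parameters.

Interactive image-analysis tools hide choices such as "which threshold did
Otsu pick" inside the GUI session.  Every operation in this package that
derives a data-dependent value (threshold, background cutoff, percentile,
gate bounds) can record it here so a run is fully reproducible from its log.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any


def _jsonable(value: Any) -> Any:
    """Coerce numpy scalars/arrays into plain JSON types."""
    if hasattr(value, "tolist"):
        return value.tolist()
    if hasattr(value, "item"):
        return value.item()
    if isinstance(value, dict):
        return {str(k): _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


@dataclass
class ProvenanceLog:
    """Append-only record of operations and their derived values."""

    records: list[dict] = field(default_factory=list)

    def record(self, op: str, params: dict | None = None, derived: dict | None = None) -> None:
        self.records.append(
            {
                "op": op,
                "params": _jsonable(params or {}),
                "derived": _jsonable(derived or {}),
            }
        )

    def write(self, path: str | Path) -> None:
        """Write the log as JSON-lines, one record per operation."""
        path = Path(path)
        with path.open("w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")

    def __len__(self) -> int:
        return len(self.records)
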