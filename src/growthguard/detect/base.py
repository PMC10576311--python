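"""Shared detection-result container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

__all__ = ["DetectionResult"]


@dataclass(frozen=True)
class DetectionResult:
    """Flags emitted by one detector (or a combination of detectors).

    ``level`` is ``"measurement"`` (flags are (subject_id, visit_index)
    cells) or ``"trajectory"`` (flags are subject_ids).  ``params`` echoes
    the configuration for provenance.
    """

    level: str
    flags: frozenset
    method: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("measurement", "trajectory"):
            raise ValueError(f"unknown level {self.level!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))
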