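"""Study-design primitives: exposure windows in days-pre-event coordinates.

All windows are closed integer intervals measured backwards from the index
event: day 1 is the day immediately before the event, so "1-50 days
pre-event" means offsets 1..50 inclusive.  A design pairs a case window
(immediately before the event) with two alternative control windows placed
earlier in the subject's history; the gaps between them are the derived
washout periods.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Mapping, Union

import yaml

logger = logging.getLogger(__name__)

#: Default design: case 1-50, CW1 101-150, CW2 151-200 days pre-event,
#: over a 200-day observation horizon.
DEFAULT_DESIGN_MAPPING: Mapping = {
    "case_window": {"start": 1, "end": 50},
    "control_window_1": {"start": 101, "end": 150},
    "control_window_2": {"start": 151, "end": 200},
    "horizon_days": 200,
}


@dataclass(frozen=True)
class WindowSpec:
    """A closed interval [start_days_pre, end_days_pre] of days before the event.

    ``start_days_pre`` is the boundary nearer the event (smaller offset);
    on a timeline drawn with the event at the right, it is the window's
    right-hand side (RHS).  ``end_days_pre`` is the far boundary (LHS).
    """

    start_days_pre: int
    end_days_pre: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start_days_pre, int) and isinstance(self.end_days_pre, int)):
            raise TypeError("window boundaries must be integers (whole days pre-event)")
        if not 1 <= self.start_days_pre < self.end_days_pre:
            raise ValueError(
                f"window requires 1 <= start < end, got "
                f"[{self.start_days_pre}, {self.end_days_pre}]"
            )

    @property
    def width(self) -> int:
        return self.end_days_pre - self.start_days_pre + 1

    def contains(self, offset: int) -> bool:
        return self.start_days_pre <= offset <= self.end_days_pre

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.start_days_pre}-{self.end_days_pre}"


@dataclass(frozen=True)
class StudyDesign:
    """Case window plus two alternative control windows over a fixed horizon.

    Invariants: case < CW1 < CW2 in days-pre-event order, pairwise disjoint,
    and the horizon covers CW2.  Washout periods are the derived gaps
    between the case window and each control window.
    """

    case_window: WindowSpec
    control_window_1: WindowSpec
    control_window_2: WindowSpec
    horizon_days: int

    def __post_init__(self) -> None:
        case, cw1, cw2 = self.case_window, self.control_window_1, self.control_window_2
        if not case.end_days_pre < cw1.start_days_pre:
            raise ValueError(
                f"control window 1 ({cw1}) must start after the case window ends ({case})"
            )
        if not cw1.end_days_pre < cw2.start_days_pre:
            raise ValueError(
                f"control window 2 ({cw2}) must start after control window 1 ends ({cw1})"
            )
        if self.horizon_days < cw2.end_days_pre:
            raise ValueError(
                f"horizon ({self.horizon_days} days) does not cover control window 2 ({cw2})"
            )
        if case.end_days_pre + 1 == cw1.start_days_pre:
            logger.warning("zero-width washout between case window and control window 1")

    def washout(self, control_window: WindowSpec) -> tuple[int, int] | None:
        """Derived washout period (inclusive day range) between the case window
        and ``control_window``; None when the windows are adjacent.  For the
        second control window this span includes the first control window,
        matching the convention that each control window's washout runs from
        the case-window edge to that control window."""
        lo = self.case_window.end_days_pre + 1
        hi = control_window.start_days_pre - 1
        return (lo, hi) if lo <= hi else None


def _coerce_window(obj, name: str) -> WindowSpec:
    if isinstance(obj, WindowSpec):
        return obj
    if isinstance(obj, Mapping):
        try:
            return WindowSpec(int(obj["start"]), int(obj["end"]))
        except KeyError as exc:
            raise ValueError(f"{name}: window mapping needs 'start' and 'end'") from exc
    if isinstance(obj, (list, tuple)) and len(obj) == 2:
        return WindowSpec(int(obj[0]), int(obj[1]))
    raise ValueError(f"{name}: cannot interpret {obj!r} as a window")


def load_design(config: Union[str, os.PathLike, Mapping, None] = None) -> StudyDesign:
    """Build a validated :class:`StudyDesign` from a mapping or a YAML/JSON file.

    With no argument, returns the default design (case 1-50, CW1 101-150,
    CW2 151-200, horizon 200 days).
    """
    if config is None:
        mapping: Mapping = DEFAULT_DESIGN_MAPPING
    elif isinstance(config, Mapping):
        mapping = config
    else:
        path = os.fspath(config)
        if not os.path.exists(path):
            raise FileNotFoundError(f"design config not found: {path}")
        with open(path) as fh:
            text = fh.read()
        mapping = (
            json.loads(text) if path.endswith(".json") else yaml.safe_load(text)
        )
        if not isinstance(mapping, Mapping):
            raise ValueError(f"design config {path} did not parse to a mapping")

    missing = {"case_window", "control_window_1", "control_window_2"} - set(mapping)
    if missing:
        raise ValueError(f"design config missing keys: {sorted(missing)}")
    case = _coerce_window(mapping["case_window"], "case_window")
    cw1 = _coerce_window(mapping["control_window_1"], "control_window_1")
    cw2 = _coerce_window(mapping["control_window_2"], "control_window_2")
    horizon = int(mapping.get("horizon_days", cw2.end_days_pre))
    return StudyDesign(case, cw1, cw2, horizon)
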