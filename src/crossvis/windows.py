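"""Exposure-status classification under alternative control windows.

A subject is *exposed* in a window iff at least one dispensing offset falls
inside it.  Crossing case-window exposure with control-window exposure gives
the four case-crossover statuses: intermittent user (case only), recent
stopper (control only), continuous user (both), non-user (neither).  Each
subject is classified once per control window; case-window exposure is a
single fact shared by both classifications.

Also provides the repeat-dispensing heuristic used to pick window lengths:
the smallest number of days within which a given percentage of patients had
a repeat dispensing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .design import StudyDesign, WindowSpec
from .io import SubjectHistory


class ExposureStatus(enum.Enum):
    INTERMITTENT = "intermittent"      # exposed in case window only
    RECENT_STOPPER = "recent_stopper"  # exposed in control window only
    CONTINUOUS = "continuous"          # exposed in both
    NON_USER = "non_user"              # exposed in neither

    def __str__(self) -> str:
        return self.value

    @property
    def exposed_case(self) -> bool:
        return self in (ExposureStatus.INTERMITTENT, ExposureStatus.CONTINUOUS)

    @property
    def discordant(self) -> bool:
        """Exposed in exactly one of the two windows; only these inform the OR."""
        return self in (ExposureStatus.INTERMITTENT, ExposureStatus.RECENT_STOPPER)


@dataclass(frozen=True)
class SubjectClassification:
    """Per-subject status under each of the two alternative control windows."""

    subject_id: str
    status_cw1: ExposureStatus
    status_cw2: ExposureStatus

    def __post_init__(self) -> None:
        # case-window exposure is one fact, so the two statuses must agree on it
        if self.status_cw1.exposed_case != self.status_cw2.exposed_case:
            raise ValueError(
                f"{self.subject_id}: inconsistent case-window exposure "
                f"({self.status_cw1} vs {self.status_cw2})"
            )

    def status(self, which: str) -> ExposureStatus:
        key = which.lower()
        if key in ("cw1", "1", "control_window_1"):
            return self.status_cw1
        if key in ("cw2", "2", "control_window_2"):
            return self.status_cw2
        raise ValueError(f"unknown control window {which!r}")


def exposed_in(history: SubjectHistory, window: WindowSpec) -> bool:
    """True iff the history has at least one offset inside the closed window."""
    return any(window.contains(off) for off in history.days_pre)


def classify_exposure(
    history: SubjectHistory,
    case_window: WindowSpec,
    control_window: WindowSpec,
) -> ExposureStatus:
    in_case = exposed_in(history, case_window)
    in_control = exposed_in(history, control_window)
    if in_case and in_control:
        return ExposureStatus.CONTINUOUS
    if in_case:
        return ExposureStatus.INTERMITTENT
    if in_control:
        return ExposureStatus.RECENT_STOPPER
    return ExposureStatus.NON_USER


def classify_cohort(
    histories: Iterable[SubjectHistory],
    design: StudyDesign,
) -> list[SubjectClassification]:
    """One classification per subject under each control window of the design."""
    return [
        SubjectClassification(
            h.subject_id,
            classify_exposure(h, design.case_window, design.control_window_1),
            classify_exposure(h, design.case_window, design.control_window_2),
        )
        for h in histories
    ]


GapPolicy = Literal["first-gap", "all-gaps", "median-gap"]


def _subject_gaps(offsets: Sequence[int], policy: GapPolicy) -> list[int]:
    # offsets are days-pre-event ascending; calendar order is the reverse,
    # so the gap between the first and second dispensing in calendar order
    # is the difference of the two largest offsets.
    diffs = [offsets[i + 1] - offsets[i] for i in range(len(offsets) - 1)]
    if policy == "first-gap":
        return [diffs[-1]]
    if policy == "all-gaps":
        return diffs
    if policy == "median-gap":
        ordered = sorted(diffs)
        mid = len(ordered) // 2
        med = ordered[mid] if len(ordered) % 2 else (ordered[mid - 1] + ordered[mid]) / 2
        return [med]
    raise ValueError(f"unknown gap policy {policy!r}")


def suggest_window_length(
    histories: Iterable[SubjectHistory],
    percentile: float = 75.0,
    gap_policy: GapPolicy = "first-gap",
) -> int:
    """Smallest whole-day span covering >= ``percentile``% of repeat-dispensing gaps.

    Per subject with at least two dispensings, extract time-to-repeat gaps
    under ``gap_policy`` ("first-gap": first-to-second dispensing in calendar
    order, the default; "all-gaps": every consecutive gap; "median-gap": the
    per-subject median).  Returns the smallest integer d such that at least
    ``percentile`` percent of the gaps are <= d — always an observed gap, so
    the answer is a whole number of days with no interpolation.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    gaps: list[float] = []
    for h in histories:
        if h.n_dispensings >= 2:
            gaps.extend(_subject_gaps(h.days_pre, gap_policy))
    if not gaps:
        raise ValueError("no subject has a repeat dispensing; cannot suggest a window length")
    gaps.sort()
    n = len(gaps)
    for i, gap in enumerate(gaps):
        if (i + 1) / n * 100 >= percentile:
            return int(gap) if float(gap).is_integer() else int(gap) + 1
    return int(gaps[-1])  # pragma: no cover - loop always covers 100%
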