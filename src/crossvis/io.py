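"""Claims-table input/output and date -> days-pre-event normalisation.

Dispensing and event tables are plain CSV with ISO-8601 civil dates
(timezone-free).  Each subject has at most one index event; dispensings
are reduced to a :class:`SubjectHistory` of distinct integer offsets in
days before that event, day 1 being the day immediately before it.
"""

from __future__ import annotations

import datetime as dt
import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .design import StudyDesign

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DispensingRecord:
    subject_id: str
    dispensing_date: dt.date


@dataclass(frozen=True)
class EventRecord:
    subject_id: str
    event_date: dt.date


@dataclass(frozen=True)
class SubjectHistory:
    """A subject's dispensings as sorted, distinct days-pre-event offsets.

    Offsets are restricted to [1, horizon]; dispensings on or after the
    event date are excluded (they cannot precede the outcome).
    """

    subject_id: str
    event_date: dt.date
    days_pre: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")
        if list(self.days_pre) != sorted(set(self.days_pre)):
            raise ValueError("days_pre must be strictly increasing")
        if self.days_pre and self.days_pre[0] < 1:
            raise ValueError("days_pre offsets must be >= 1")

    @property
    def n_dispensings(self) -> int:
        return len(self.days_pre)

    def latest_offset(self) -> int | None:
        """Most recent dispensing = smallest days-pre-event offset."""
        return self.days_pre[0] if self.days_pre else None

    def earliest_offset(self) -> int | None:
        """Oldest dispensing = largest days-pre-event offset."""
        return self.days_pre[-1] if self.days_pre else None


def _parse_date(value, row_number: int, path: str) -> dt.date:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValueError(
            f"{path}: unparseable ISO-8601 date {value!r} at file row {row_number}"
        ) from exc


def _read_table(path, subject_col: str, date_col: str) -> pd.DataFrame:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"input file not found: {path}")
    frame = pd.read_csv(path, dtype=str)
    missing = {subject_col, date_col} - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return frame


def read_dispensings(
    path,
    subject_col: str = "subject_id",
    date_col: str = "dispensing_date",
) -> list[DispensingRecord]:
    """Read a dispensing table; malformed dates raise with the file row number."""
    frame = _read_table(path, subject_col, date_col)
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        sid = str(getattr(row, subject_col)).strip()
        if not sid or sid == "nan":
            raise ValueError(f"{path}: empty subject id at file row {i + 2}")
        date = _parse_date(getattr(row, date_col), i + 2, os.fspath(path))
        records.append(DispensingRecord(sid, date))
    return records


def read_events(
    path,
    subject_col: str = "subject_id",
    date_col: str = "event_date",
) -> list[EventRecord]:
    """Read the index-event table; duplicate subject ids are an error."""
    frame = _read_table(path, subject_col, date_col)
    records, seen = [], set()
    for i, row in enumerate(frame.itertuples(index=False)):
        sid = str(getattr(row, subject_col)).strip()
        if not sid or sid == "nan":
            raise ValueError(f"{path}: empty subject id at file row {i + 2}")
        if sid in seen:
            dupes = frame[subject_col][frame[subject_col].duplicated(keep=False)]
            raise ValueError(
                f"{path}: duplicate event rows for subject(s) "
                f"{sorted(set(dupes))} — one index event per subject"
            )
        seen.add(sid)
        records.append(EventRecord(sid, _parse_date(getattr(row, date_col), i + 2, os.fspath(path))))
    return records


def build_histories(
    dispensings: Iterable[DispensingRecord],
    events: Sequence[EventRecord],
    design: StudyDesign,
) -> list[SubjectHistory]:
    """Normalise calendar dates to days-pre-event offsets, one history per subject.

    Offsets outside [1, horizon] are dropped (counted in a logged warning),
    same-day duplicates collapse to one binary exposure marker, and subjects
    with dispensings but no event are skipped with a warning.  Subjects with
    an event and no dispensings are retained with an empty history.
    Output order and content are invariant to input row order.
    """
    event_by_subject = {e.subject_id: e.event_date for e in events}
    offsets: dict[str, set[int]] = {sid: set() for sid in event_by_subject}
    kept = dropped = 0
    skipped_subjects: set[str] = set()
    for rec in dispensings:
        event_date = event_by_subject.get(rec.subject_id)
        if event_date is None:
            skipped_subjects.add(rec.subject_id)
            continue
        offset = (event_date - rec.dispensing_date).days
        if 1 <= offset <= design.horizon_days:
            offsets[rec.subject_id].add(offset)
            kept += 1
        else:
            dropped += 1
    if skipped_subjects:
        logger.warning(
            "skipped dispensings for %d subject(s) with no event record: %s",
            len(skipped_subjects), sorted(skipped_subjects)[:10],
        )
    if dropped:
        logger.warning(
            "dropped %d dispensing(s) outside days 1-%d pre-event (kept %d)",
            dropped, design.horizon_days, kept,
        )
    return [
        SubjectHistory(sid, event_by_subject[sid], tuple(sorted(offs)))
        for sid, offs in sorted(offsets.items())
    ]


def write_dispensings(records: Iterable[DispensingRecord], path) -> None:
    pd.DataFrame(
        [(r.subject_id, r.dispensing_date.isoformat()) for r in records],
        columns=["subject_id", "dispensing_date"],
    ).to_csv(path, index=False)


def write_events(records: Iterable[EventRecord], path) -> None:
    pd.DataFrame(
        [(r.subject_id, r.event_date.isoformat()) for r in records],
        columns=["subject_id", "event_date"],
    ).to_csv(path, index=False)
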