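"""Seeded synthetic claims generator with known exposure-archetype structure.

Emulates the dispensing patterns a claims extract would show over the
pre-event horizon: continuous refillers (regular refill gaps covering the
whole horizon), short-course intermittent users (a course planted in one
window), recent stoppers (a course in a control window, nothing later),
washout-only users, and non-users.  Every stage of the pipeline —
classification, stratification, rule evaluation, odds ratios,
visualisation — is testable against the generator's truth table without
any real data.

The truth table is *recomputed from the emitted offsets*, never taken on
faith from the archetype label, so stochastic jitter that genuinely moves
a subject's status is reflected in the truth.  All randomness flows
through one numpy Generator, so a fixed seed gives byte-identical output.
"""

from __future__ import annotations

import datetime as dt
import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .design import StudyDesign, WindowSpec
from .io import DispensingRecord, EventRecord, SubjectHistory
from .strata import Stratum, assign_stratum
from .windows import ExposureStatus, SubjectClassification, classify_exposure

logger = logging.getLogger(__name__)


class Archetype(enum.Enum):
    CONTINUOUS_REFILLER = "continuous_refiller"
    INTERMITTENT_CASE_USER = "intermittent_case_user"
    RECENT_STOPPER = "recent_stopper"
    NON_USER = "non_user"
    WASHOUT_ONLY_USER = "washout_only_user"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class ArchetypeSpec:
    """How many subjects of one archetype to plant, and with what timing.

    ``course_window`` is where a short course is planted (intermittent and
    stopper archetypes; defaults: case window, control window 1) or, for
    refillers, the window containing the *earliest* dispensing — planting a
    refiller's onset inside CW1 builds the persistent-user-bias case, a
    subject continuous under CW1 but intermittent under CW2.
    ``refill_gap_mean``/``refill_gap_sd`` are the refill-interval
    distribution in days (Normal truncated to >= 1 day); ``jitter_days``
    shifts each planted course offset uniformly in +/- that many days.
    """

    archetype: Archetype
    count: int
    refill_gap_mean: float = 30.0
    refill_gap_sd: float = 0.0
    course_window: WindowSpec | None = None
    jitter_days: int = 0
    course_size: tuple[int, int] = (1, 2)

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.refill_gap_mean <= 0:
            raise ValueError("refill_gap_mean must be positive (days)")
        if self.jitter_days < 0:
            raise ValueError("jitter_days must be >= 0")


@dataclass(frozen=True)
class TruthRecord:
    """Planted archetype plus statuses/stratum recomputed from emitted offsets."""

    subject_id: str
    archetype: Archetype
    status_cw1: ExposureStatus
    status_cw2: ExposureStatus
    stratum: Stratum


def _draw_gap(rng: np.random.Generator, mean: float, sd: float) -> int:
    gap = mean if sd == 0 else rng.normal(mean, sd)
    return max(1, int(round(gap)))


def _refiller_offsets(rng, spec: ArchetypeSpec, design: StudyDesign) -> set[int]:
    # walk from the onset (earliest dispensing) toward the event
    if spec.course_window is not None:
        onset = int(rng.integers(spec.course_window.start_days_pre,
                                 spec.course_window.end_days_pre + 1))
    else:
        slack = max(1, int(round(spec.refill_gap_mean)))
        onset = design.horizon_days - int(rng.integers(0, slack))
    offsets = set()
    t = onset
    while t >= 1:
        offsets.add(t)
        t -= _draw_gap(rng, spec.refill_gap_mean, spec.refill_gap_sd)
    return offsets


def _course_offsets(rng, window: WindowSpec, spec: ArchetypeSpec, design: StudyDesign) -> set[int]:
    lo_n, hi_n = spec.course_size
    n = int(rng.integers(lo_n, hi_n + 1))
    n = min(n, window.width)
    days = rng.choice(np.arange(window.start_days_pre, window.end_days_pre + 1),
                      size=n, replace=False)
    offsets = set()
    for d in days:
        d = int(d)
        if spec.jitter_days:
            d += int(rng.integers(-spec.jitter_days, spec.jitter_days + 1))
        if 1 <= d <= design.horizon_days:
            offsets.add(d)
    return offsets


def _spec_offsets(rng, spec: ArchetypeSpec, design: StudyDesign) -> set[int]:
    if spec.course_window is not None and spec.course_window.end_days_pre > design.horizon_days:
        raise ValueError(
            f"course window {spec.course_window} lies outside the "
            f"{design.horizon_days}-day horizon"
        )
    a = spec.archetype
    if a is Archetype.NON_USER:
        return set()
    if a is Archetype.CONTINUOUS_REFILLER:
        return _refiller_offsets(rng, spec, design)
    if a is Archetype.INTERMITTENT_CASE_USER:
        window = spec.course_window or design.case_window
        return _course_offsets(rng, window, spec, design)
    if a is Archetype.RECENT_STOPPER:
        window = spec.course_window or design.control_window_1
        return _course_offsets(rng, window, spec, design)
    if a is Archetype.WASHOUT_ONLY_USER:
        washout = design.washout(design.control_window_1)
        if washout is None:
            raise ValueError("design has no washout period to plant dispensings in")
        window = spec.course_window or WindowSpec(*washout)
        return _course_offsets(rng, window, spec, design)
    raise ValueError(f"unknown archetype {a!r}")


def generate_cohort(
    specs: Sequence[ArchetypeSpec],
    design: StudyDesign,
    seed: int,
    *,
    event_date_range: tuple[str, str] = ("2009-01-01", "2012-12-31"),
    id_prefix: str = "S",
) -> tuple[list[DispensingRecord], list[EventRecord], list[TruthRecord]]:
    """Generate dispensing/event tables plus a truth table for the given specs.

    Event dates are arbitrary civil dates sampled uniformly over
    ``event_date_range``, distinct across subjects whenever the range allows.
    The truth table's statuses and stratum come from re-classifying the
    emitted offsets under ``design``, so they are correct even when jitter
    moves a course across a window boundary.
    """
    rng = np.random.default_rng(seed)
    n_total = sum(s.count for s in specs)
    d0 = dt.date.fromisoformat(event_date_range[0])
    d1 = dt.date.fromisoformat(event_date_range[1])
    span = (d1 - d0).days + 1
    if span <= 0:
        raise ValueError("event_date_range must be non-empty")
    if n_total <= span:
        day_idx = rng.choice(span, size=n_total, replace=False)
    else:
        logger.warning(
            "more subjects (%d) than days in the event date range (%d); "
            "event dates will repeat", n_total, span,
        )
        day_idx = rng.integers(0, span, size=n_total)

    width = max(4, len(str(max(n_total, 1))))
    dispensings: list[DispensingRecord] = []
    events: list[EventRecord] = []
    truth: list[TruthRecord] = []
    subject_no = 0
    for spec in specs:
        for _ in range(spec.count):
            sid = f"{id_prefix}{subject_no:0{width}d}"
            event_date = d0 + dt.timedelta(days=int(day_idx[subject_no]))
            subject_no += 1
            offsets = sorted(_spec_offsets(rng, spec, design))
            for off in offsets:
                dispensings.append(
                    DispensingRecord(sid, event_date - dt.timedelta(days=off))
                )
            events.append(EventRecord(sid, event_date))
            history = SubjectHistory(sid, event_date, tuple(offsets))
            s1 = classify_exposure(history, design.case_window, design.control_window_1)
            s2 = classify_exposure(history, design.case_window, design.control_window_2)
            stratum = assign_stratum(SubjectClassification(sid, s1, s2))
            truth.append(TruthRecord(sid, spec.archetype, s1, s2, stratum))
    return dispensings, events, truth


@dataclass(frozen=True)
class TruthReport:
    """Planted-vs-computed status agreement, per control window."""

    n_subjects: int
    n_agree_cw1: int
    n_agree_cw2: int
    confusion_cw1: Mapping[tuple[ExposureStatus, ExposureStatus], int]
    confusion_cw2: Mapping[tuple[ExposureStatus, ExposureStatus], int]

    @property
    def agreement_cw1(self) -> float:
        return self.n_agree_cw1 / self.n_subjects if self.n_subjects else 1.0

    @property
    def agreement_cw2(self) -> float:
        return self.n_agree_cw2 / self.n_subjects if self.n_subjects else 1.0


def verify_truth(
    truth: Iterable[TruthRecord],
    classifications: Iterable[SubjectClassification],
) -> TruthReport:
    """Cross-tabulate planted statuses against pipeline-computed ones."""
    computed = {c.subject_id: c for c in classifications}
    conf1: dict[tuple[ExposureStatus, ExposureStatus], int] = {}
    conf2: dict[tuple[ExposureStatus, ExposureStatus], int] = {}
    n = agree1 = agree2 = 0
    for t in truth:
        c = computed.get(t.subject_id)
        if c is None:
            raise ValueError(f"truth subject {t.subject_id} missing from classifications")
        n += 1
        conf1[(t.status_cw1, c.status_cw1)] = conf1.get((t.status_cw1, c.status_cw1), 0) + 1
        conf2[(t.status_cw2, c.status_cw2)] = conf2.get((t.status_cw2, c.status_cw2), 0) + 1
        agree1 += t.status_cw1 is c.status_cw1
        agree2 += t.status_cw2 is c.status_cw2
    return TruthReport(n, agree1, agree2, conf1, conf2)


def load_archetype_specs(source, design: StudyDesign) -> list[ArchetypeSpec]:
    """Parse archetype specs from a YAML file or mapping (CLI `simulate` input).

    Expected shape: ``{archetypes: [{archetype, count, refill_gap_mean?,
    refill_gap_sd?, course_window? {start,end}, jitter_days?}, ...]}``.
    """
    if isinstance(source, Mapping):
        mapping = source
    else:
        with open(source) as fh:
            mapping = yaml.safe_load(fh)
    if not isinstance(mapping, Mapping) or "archetypes" not in mapping:
        raise ValueError("archetype spec must be a mapping with an 'archetypes' list")
    specs = []
    for entry in mapping["archetypes"]:
        cw = entry.get("course_window")
        specs.append(ArchetypeSpec(
            archetype=Archetype(str(entry["archetype"]).lower()),
            count=int(entry["count"]),
            refill_gap_mean=float(entry.get("refill_gap_mean", 30.0)),
            refill_gap_sd=float(entry.get("refill_gap_sd", 0.0)),
            course_window=WindowSpec(int(cw["start"]), int(cw["end"])) if cw else None,
            jitter_days=int(entry.get("jitter_days", 0)),
        ))
    return specs


def write_truth(truth: Iterable[TruthRecord], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [(t.subject_id, str(t.archetype), str(t.status_cw1), str(t.status_cw2), str(t.stratum))
         for t in truth],
        columns=["subject_id", "archetype", "status_cw1", "status_cw2", "stratum"],
    ).to_csv(path, index=False)
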