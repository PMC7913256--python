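"""Cross-window stratification and the deterministic misclassification rules.

Subjects are stratified by how their exposure status changes when control
window two (CW2) replaces control window one (CW1).  Six strata (A-F)
feature a change relevant to misclassification; two (G, H) do not and are
not assessed:

    A  recent stopper  -> non-user          E  continuous    -> intermittent
    B  non-user        -> recent stopper    F  intermittent  -> intermittent
    C  recent stopper  -> recent stopper    G  continuous    -> continuous
    D  intermittent    -> continuous        H  non-user      -> non-user

Each assessed stratum carries one deterministic rule that decides, for the
*whole stratum*, which control window classifies its members correctly.
Every rule asks whether a strict majority of members satisfy a condition
about where a reference dispensing sits relative to a window boundary.  On
a timeline drawn with the event at the right, a window's RHS is the
boundary nearer the event (its start in days-pre-event) and its LHS the
far boundary (its end); a dispensing clustered near a window in which the
subject was called unexposed signals potential misclassification.

The reference dispensing is the latest (smallest offset) for strata A-C,
whose members are unexposed in the case window, and the earliest (largest
offset) for strata D-F, whose members are unexposed in the control
window(s).  Rule B instead asks whether the member had any dispensing in
the washout period.  Equidistant ties count as *not* closer, and "greater
than half" is a strict majority; both choices are conservative and the
per-subject margins are exported so the majority can be audited.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

from .design import StudyDesign, WindowSpec
from .io import SubjectHistory
from .windows import ExposureStatus, SubjectClassification, classify_exposure

logger = logging.getLogger(__name__)

_S = ExposureStatus


class Stratum(enum.Enum):
    A = "A"  # recent stopper -> non-user
    B = "B"  # non-user -> recent stopper
    C = "C"  # recent stopper -> recent stopper
    D = "D"  # intermittent -> continuous
    E = "E"  # continuous -> intermittent
    F = "F"  # intermittent -> intermittent
    G = "G"  # continuous -> continuous (not assessed)
    H = "H"  # non-user -> non-user (not assessed)

    def __str__(self) -> str:
        return self.value

    @property
    def assessed(self) -> bool:
        return self in ASSESSED_STRATA


ASSESSED_STRATA = (Stratum.A, Stratum.B, Stratum.C, Stratum.D, Stratum.E, Stratum.F)

_STATUS_PAIR_TO_STRATUM: dict[tuple[ExposureStatus, ExposureStatus], Stratum] = {
    (_S.RECENT_STOPPER, _S.NON_USER): Stratum.A,
    (_S.NON_USER, _S.RECENT_STOPPER): Stratum.B,
    (_S.RECENT_STOPPER, _S.RECENT_STOPPER): Stratum.C,
    (_S.INTERMITTENT, _S.CONTINUOUS): Stratum.D,
    (_S.CONTINUOUS, _S.INTERMITTENT): Stratum.E,
    (_S.INTERMITTENT, _S.INTERMITTENT): Stratum.F,
    (_S.CONTINUOUS, _S.CONTINUOUS): Stratum.G,
    (_S.NON_USER, _S.NON_USER): Stratum.H,
}


class Verdict(enum.Enum):
    CORRECT = "correct"
    MISCLASSIFIED = "misclassified"
    INDETERMINATE = "indeterminate"

    def __str__(self) -> str:
        return self.value


Side = Literal["LHS", "RHS"]


def assign_stratum(classification: SubjectClassification) -> Stratum:
    """Map a (CW1 status, CW2 status) pair to its unique stratum A-H."""
    pair = (classification.status_cw1, classification.status_cw2)
    try:
        return _STATUS_PAIR_TO_STRATUM[pair]
    except KeyError:
        raise ValueError(
            f"{classification.subject_id}: inadmissible status pair "
            f"({pair[0]}, {pair[1]}) — case-window exposure cannot differ "
            f"between control-window classifications"
        ) from None


def stratify(classifications: Iterable[SubjectClassification]) -> dict[Stratum, list[str]]:
    """Group subject ids by stratum; every stratum A-H is present (possibly empty)."""
    groups: dict[Stratum, list[str]] = {s: [] for s in Stratum}
    for c in classifications:
        groups[assign_stratum(c)].append(c.subject_id)
    return groups


def boundary_distance(offset: int, window: WindowSpec, side: Side) -> int:
    """Absolute distance in days from an offset to one window boundary.

    RHS = the boundary nearer the event (``start_days_pre``); LHS = the far
    boundary (``end_days_pre``) — the orientation of a timeline with the
    event at the right.
    """
    if not isinstance(offset, int) or isinstance(offset, bool):
        raise TypeError(f"offset must be an integer day count, got {offset!r}")
    boundary = window.start_days_pre if side == "RHS" else window.end_days_pre
    return abs(offset - boundary)


@dataclass(frozen=True)
class RuleDecision:
    """Outcome of one stratum's rule: a single verdict pair for the whole group.

    ``per_subject_metric`` holds (subject_id, margin): for distance rules the
    signed margin far-distance minus near-distance (positive = strictly
    closer to the rule's target boundary, zero = tie, counted as not met);
    for rule B the washout dispensing count; for rule F an indicator that
    the earliest dispensing lies in the case window.
    """

    stratum: Stratum
    n_members: int
    n_meeting_condition: int
    condition_met: bool
    verdict_cw1: Verdict
    verdict_cw2: Verdict
    per_subject_metric: tuple[tuple[str, float], ...] = field(default_factory=tuple)
    n_units: int | None = None  # counting units (members, or dispensings in per-dispensing mode)

    def __post_init__(self) -> None:
        units = self.n_units if self.n_units is not None else self.n_members
        if self.n_meeting_condition > units:
            raise ValueError("n_meeting_condition cannot exceed the number of counted units")


# verdict pairs (cw1, cw2) for each rule branch: met / not met
_VERDICTS = {
    Stratum.A: ((Verdict.CORRECT, Verdict.MISCLASSIFIED), (Verdict.MISCLASSIFIED, Verdict.CORRECT)),
    Stratum.B: ((Verdict.MISCLASSIFIED, Verdict.CORRECT), (Verdict.CORRECT, Verdict.MISCLASSIFIED)),
    Stratum.C: ((Verdict.CORRECT, Verdict.CORRECT), (Verdict.MISCLASSIFIED, Verdict.MISCLASSIFIED)),
    Stratum.D: ((Verdict.MISCLASSIFIED, Verdict.CORRECT), (Verdict.CORRECT, Verdict.MISCLASSIFIED)),
    Stratum.E: ((Verdict.CORRECT, Verdict.MISCLASSIFIED), (Verdict.MISCLASSIFIED, Verdict.CORRECT)),
    Stratum.F: ((Verdict.CORRECT, Verdict.CORRECT), (Verdict.MISCLASSIFIED, Verdict.MISCLASSIFIED)),
}


def _distance_margin(offset: int, near: tuple[WindowSpec, Side], far: tuple[WindowSpec, Side]) -> float:
    """Signed margin: positive iff strictly closer to the ``near`` boundary."""
    return boundary_distance(offset, far[0], far[1]) - boundary_distance(offset, near[0], near[1])


def _rule_margin(stratum: Stratum, history: SubjectHistory, design: StudyDesign) -> float:
    """Per-member metric whose strict positivity means the rule condition holds."""
    case, cw1, cw2 = design.case_window, design.control_window_1, design.control_window_2
    if stratum is Stratum.B:
        washout = design.washout(cw1)
        if washout is None:
            return 0.0
        lo, hi = washout
        return float(sum(1 for off in history.days_pre if lo <= off <= hi))
    if stratum in (Stratum.A, Stratum.C):
        ref = history.latest_offset()
    else:
        ref = history.earliest_offset()
    if ref is None:
        # only possible for rule B members, handled above; defensive default
        return 0.0
    if stratum is Stratum.A:
        return _distance_margin(ref, (cw1, "RHS"), (cw1, "LHS"))
    if stratum is Stratum.C:
        return _distance_margin(ref, (cw1, "RHS"), (cw2, "LHS"))
    if stratum is Stratum.D:
        return _distance_margin(ref, (cw2, "RHS"), (cw2, "LHS"))
    if stratum is Stratum.E:
        return _distance_margin(ref, (cw1, "LHS"), (cw1, "RHS"))
    if stratum is Stratum.F:
        return 1.0 if case.contains(ref) else 0.0
    raise ValueError(f"stratum {stratum} has no rule (not assessed)")


def evaluate_rule(
    stratum: Stratum,
    members: Sequence[SubjectHistory],
    design: StudyDesign,
    *,
    count_mode: Literal["member", "dispensing"] = "member",
    validate: bool = True,
) -> RuleDecision:
    """Apply the stratum's rule to its members and return the group verdict.

    ``count_mode='member'`` (default) counts one reference dispensing per
    member; ``'dispensing'`` counts every dispensing of every member for the
    distance rules A, C, D, E (B and F are inherently member-level).  The
    condition is met when a strict majority of counted units satisfy it.
    ``validate`` checks that each member's recomputed classification maps to
    ``stratum`` (disable only for arithmetic exploration on fixtures).
    """
    if stratum not in _VERDICTS:
        raise ValueError(f"stratum {stratum} is not assessed (no rule defined)")
    if validate:
        for h in members:
            cls = SubjectClassification(
                h.subject_id,
                classify_exposure(h, design.case_window, design.control_window_1),
                classify_exposure(h, design.case_window, design.control_window_2),
            )
            actual = assign_stratum(cls)
            if actual is not stratum:
                raise ValueError(
                    f"member {h.subject_id} belongs to stratum {actual}, not {stratum}"
                )
    n_members = len(members)
    if n_members == 0:
        return RuleDecision(stratum, 0, 0, False, Verdict.INDETERMINATE, Verdict.INDETERMINATE)

    metrics = tuple((h.subject_id, _rule_margin(stratum, h, design)) for h in members)
    if count_mode == "dispensing" and stratum in (Stratum.A, Stratum.C, Stratum.D, Stratum.E):
        unit_margins = [
            _per_dispensing_margin(stratum, off, design)
            for h in members
            for off in h.days_pre
        ]
    elif count_mode in ("member", "dispensing"):
        unit_margins = [m for _, m in metrics]
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")

    n_units = len(unit_margins)
    n_meeting = sum(1 for m in unit_margins if m > 0)
    met = n_meeting > n_units / 2  # strict majority; exact half = not met
    verdict_cw1, verdict_cw2 = _VERDICTS[stratum][0 if met else 1]
    if not met and stratum in (Stratum.C, Stratum.F):
        logger.warning(
            "stratum %s majority condition not met: members judged misclassified "
            "under BOTH control windows", stratum,
        )
    return RuleDecision(
        stratum, n_members, n_meeting, met, verdict_cw1, verdict_cw2,
        per_subject_metric=metrics, n_units=n_units,
    )


def _per_dispensing_margin(stratum: Stratum, offset: int, design: StudyDesign) -> float:
    cw1, cw2 = design.control_window_1, design.control_window_2
    if stratum is Stratum.A:
        return _distance_margin(offset, (cw1, "RHS"), (cw1, "LHS"))
    if stratum is Stratum.C:
        return _distance_margin(offset, (cw1, "RHS"), (cw2, "LHS"))
    if stratum is Stratum.D:
        return _distance_margin(offset, (cw2, "RHS"), (cw2, "LHS"))
    return _distance_margin(offset, (cw1, "LHS"), (cw1, "RHS"))  # E


def evaluate_all(
    histories: Iterable[SubjectHistory],
    classifications: Iterable[SubjectClassification],
    design: StudyDesign,
    **kwargs,
) -> dict[Stratum, RuleDecision]:
    """Evaluate every assessed stratum's rule over a classified cohort."""
    by_id = {h.subject_id: h for h in histories}
    groups = stratify(classifications)
    decisions = {}
    for stratum in ASSESSED_STRATA:
        members = []
        for sid in groups[stratum]:
            if sid not in by_id:
                raise ValueError(f"classified subject {sid} has no dispensing history")
            members.append(by_id[sid])
        decisions[stratum] = evaluate_rule(stratum, members, design, **kwargs)
    return decisions


@dataclass(frozen=True)
class MisclassSummary:
    """Cohort-level percent correctly/potentially mis-classified per window.

    The denominator is the number of subjects in the assessed strata A-F —
    the union of subjects discordant under either control window.  A
    stratum's whole size counts toward "correct" or "misclassified"
    according to its group verdict for that window; empty strata are
    indeterminate and contribute nothing.
    """

    stratum_sizes: Mapping[Stratum, int]
    verdicts_cw1: Mapping[Stratum, Verdict]
    verdicts_cw2: Mapping[Stratum, Verdict]
    denominator: int
    percent_correct_cw1: float
    percent_misclassified_cw1: float
    percent_indeterminate_cw1: float
    percent_correct_cw2: float
    percent_misclassified_cw2: float
    percent_indeterminate_cw2: float


def summarize(
    decisions: Mapping[Stratum, RuleDecision],
    stratum_sizes: Mapping[Stratum, int] | None = None,
    denominator: int | None = None,
) -> MisclassSummary:
    """Aggregate stratum verdicts into percent correct / misclassified per window."""
    if stratum_sizes is None:
        stratum_sizes = {s: d.n_members for s, d in decisions.items()}
    sizes = {s: stratum_sizes.get(s, 0) for s in ASSESSED_STRATA}
    if denominator is None:
        denominator = sum(sizes.values())
    if denominator <= 0:
        raise ValueError("denominator is zero: no subjects in assessed strata A-F")

    def pct(verdict_of, target: Verdict) -> float:
        return 100.0 * sum(
            sizes[s] for s in ASSESSED_STRATA
            if s in decisions and verdict_of(decisions[s]) is target
        ) / denominator

    return MisclassSummary(
        stratum_sizes=sizes,
        verdicts_cw1={s: decisions[s].verdict_cw1 for s in decisions},
        verdicts_cw2={s: decisions[s].verdict_cw2 for s in decisions},
        denominator=denominator,
        percent_correct_cw1=pct(lambda d: d.verdict_cw1, Verdict.CORRECT),
        percent_misclassified_cw1=pct(lambda d: d.verdict_cw1, Verdict.MISCLASSIFIED),
        percent_indeterminate_cw1=pct(lambda d: d.verdict_cw1, Verdict.INDETERMINATE),
        percent_correct_cw2=pct(lambda d: d.verdict_cw2, Verdict.CORRECT),
        percent_misclassified_cw2=pct(lambda d: d.verdict_cw2, Verdict.MISCLASSIFIED),
        percent_indeterminate_cw2=pct(lambda d: d.verdict_cw2, Verdict.INDETERMINATE),
    )
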