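"""Discordant-pair case-crossover estimation.

With a 1:1 self-matched design and binary exposure, only discordant
subjects inform the odds ratio: OR = b/c, where b is the number exposed in
the case window only (intermittent users) and c the number exposed in the
control window only (recent stoppers).  This ratio is the exact maximiser
of the conditional likelihood of a univariable conditional logistic
regression with subjects as strata, so the closed form replaces the model
fit.  The confidence interval is Wald on the log scale:

    CI = exp( ln(b/c) +/- z_{1-alpha/2} * sqrt(1/b + 1/c) )

Concordant subjects (continuous users, non-users) are tallied for
reporting but cancel out of the conditional likelihood.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from scipy import stats as _sps

from .windows import ExposureStatus, SubjectClassification


@dataclass(frozen=True)
class DiscordantCounts:
    """Four-way exposure tally for one choice of control window."""

    n_continuous: int
    n_non_user: int
    n_intermittent: int
    n_recent_stopper: int
    control_window_label: str = ""

    def __post_init__(self) -> None:
        for name in ("n_continuous", "n_non_user", "n_intermittent", "n_recent_stopper"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_continuous + self.n_non_user + self.n_intermittent + self.n_recent_stopper

    @property
    def n_discordant(self) -> int:
        return self.n_intermittent + self.n_recent_stopper


@dataclass(frozen=True)
class ORResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    alpha: float
    method: str = "discordant-pair ratio, Wald log-OR CI"

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.odds_ratio <= self.ci_upper:
            raise ValueError("confidence interval must bracket the odds ratio")


def discordant_counts(
    classifications: Iterable[SubjectClassification],
    which_window: str,
) -> DiscordantCounts:
    """Tally the four exposure statuses for one control window ('CW1' or 'CW2')."""
    tallies = {status: 0 for status in ExposureStatus}
    for c in classifications:
        tallies[c.status(which_window)] += 1
    return DiscordantCounts(
        n_continuous=tallies[ExposureStatus.CONTINUOUS],
        n_non_user=tallies[ExposureStatus.NON_USER],
        n_intermittent=tallies[ExposureStatus.INTERMITTENT],
        n_recent_stopper=tallies[ExposureStatus.RECENT_STOPPER],
        control_window_label=which_window.upper(),
    )


def odds_ratio(
    counts: DiscordantCounts,
    alpha: float = 0.05,
    *,
    continuity_correction: bool = False,
) -> ORResult:
    """Odds ratio and Wald CI from discordant counts.

    A zero discordant cell makes the estimate degenerate (OR of 0 or
    infinity, unbounded CI); this raises unless ``continuity_correction``
    opts in to the Haldane-Anscombe +0.5 adjustment of both discordant
    cells.  Returned values are unrounded.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    b = float(counts.n_intermittent)
    c = float(counts.n_recent_stopper)
    if b == 0 or c == 0:
        if not continuity_correction:
            raise ValueError(
                f"degenerate discordant table (intermittent={int(b)}, "
                f"recent stoppers={int(c)}): the odds ratio is 0 or infinite and "
                f"the conditional likelihood has no interior maximum; pass "
                f"continuity_correction=True for the Haldane-Anscombe +0.5 estimate"
            )
        b += 0.5
        c += 0.5
        method = "discordant-pair ratio (+0.5 continuity correction), Wald log-OR CI"
    else:
        method = "discordant-pair ratio, Wald log-OR CI"
    or_hat = b / c
    z = _sps.norm.ppf(1 - alpha / 2)
    se = math.sqrt(1.0 / b + 1.0 / c)
    return ORResult(
        odds_ratio=or_hat,
        ci_lower=math.exp(math.log(or_hat) - z * se),
        ci_upper=math.exp(math.log(or_hat) + z * se),
        alpha=alpha,
        method=method,
    )


def analyze(
    classifications: Iterable[SubjectClassification],
    alpha: float = 0.05,
    **kwargs,
) -> dict[str, tuple[DiscordantCounts, ORResult]]:
    """Counts and OR/CI for both control windows (the Table-3-style report)."""
    classifications = list(classifications)
    out = {}
    for label in ("CW1", "CW2"):
        counts = discordant_counts(classifications, label)
        out[label] = (counts, odds_ratio(counts, alpha, **kwargs))
    return out
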