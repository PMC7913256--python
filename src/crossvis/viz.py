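"""Stratified dispensing-timeline visualisation.

One panel per assessed stratum (A-F by default), one horizontal row per
subject, a marker per dispensing, with the case window, washout(s) and both
control windows shaded.  The x axis is days pre-event with the event at the
*right*, so a window's right-hand side is its boundary nearer the event —
the orientation under which the stratum rules' RHS/LHS language is literal.

Within-panel sorting follows the method's conventions: strata A-C (members
unexposed in the case window) are ordered by their latest dispensing,
nearest the case window first; strata D-F (unexposed in the control
windows) by their earliest dispensing, nearest the far control side first.
Ties break by subject id, so the layout is deterministic and the TSV
export is byte-identical across runs — the testable surface, independent
of visual styling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .design import StudyDesign
from .io import SubjectHistory
from .strata import ASSESSED_STRATA, RuleDecision, Stratum, stratify
from .windows import SubjectClassification


@dataclass(frozen=True)
class PanelRow:
    subject_id: str
    row_index: int
    offsets: tuple[int, ...]


@dataclass(frozen=True)
class Panel:
    stratum: Stratum
    rows: tuple[PanelRow, ...]
    decision: RuleDecision | None = None

    @property
    def n(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class PanelLayout:
    """Machine-readable figure layout: ordered panels plus window annotations."""

    panels: tuple[Panel, ...]
    design: StudyDesign
    denominator: int = 0
    orientation: str = "event-right"
    band_ranges: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return sum(p.n for p in self.panels)


def sort_stratum(stratum: Stratum, members: Sequence[SubjectHistory]) -> list[SubjectHistory]:
    """Order a stratum's members by the method's sorting convention.

    A/B/C: latest dispensing ascending (nearest the case window at top);
    D/E/F: earliest dispensing descending (nearest the far control side at
    top).  Members with no dispensings sort last; ties break by subject id.
    """
    if stratum in (Stratum.A, Stratum.B, Stratum.C):
        def key(h: SubjectHistory):
            ref = h.latest_offset()
            return (ref is None, ref if ref is not None else 0, h.subject_id)
    else:
        def key(h: SubjectHistory):
            ref = h.earliest_offset()
            return (ref is None, -(ref if ref is not None else 0), h.subject_id)
    return sorted(members, key=key)


def build_panels(
    histories: Iterable[SubjectHistory],
    classifications: Iterable[SubjectClassification],
    decisions: Mapping[Stratum, RuleDecision] | None = None,
    design: StudyDesign | None = None,
    panel_order: Sequence[Stratum] = ASSESSED_STRATA,
) -> PanelLayout:
    """Assemble the sorted per-stratum panels for the assessed strata."""
    if design is None:
        raise ValueError("a StudyDesign is required to annotate the layout")
    by_id = {h.subject_id: h for h in histories}
    groups = stratify(classifications)
    panels = []
    for stratum in panel_order:
        members = []
        for sid in groups[stratum]:
            if sid not in by_id:
                raise ValueError(f"classified subject {sid} has no dispensing history")
            members.append(by_id[sid])
        ordered = sort_stratum(stratum, members)
        rows = tuple(
            PanelRow(h.subject_id, i, tuple(sorted(h.days_pre)))
            for i, h in enumerate(ordered)
        )
        panels.append(Panel(stratum, rows, decisions.get(stratum) if decisions else None))

    bands = {"case": (design.case_window.start_days_pre, design.case_window.end_days_pre),
             "CW1": (design.control_window_1.start_days_pre, design.control_window_1.end_days_pre),
             "CW2": (design.control_window_2.start_days_pre, design.control_window_2.end_days_pre)}
    w1 = design.washout(design.control_window_1)
    if w1:
        bands["washout"] = w1
    denominator = sum(p.n for p in panels)
    return PanelLayout(tuple(panels), design, denominator, band_ranges=bands)


_BAND_COLORS = {"case": "#f4c7c3", "washout": "#eeeeee", "CW1": "#c3d7f4", "CW2": "#c9e7c5"}


def render(
    layout: PanelLayout,
    path=None,
    format: str = "svg",
    *,
    marker: str = "|",
    band_colors: Mapping[str, str] | None = None,
    figsize: tuple[float, float] | None = None,
    dpi: int = 150,
):
    """Render the layout to SVG or PNG (or return the figure when path=None).

    Markers are drawn at x = horizon - offset so that day 1 sits at the
    right edge; axis tick labels show days pre-event.
    """
    if layout.n_subjects == 0:
        raise ValueError("empty layout: no subjects in any assessed stratum")
    if format not in ("svg", "png"):
        raise ValueError(f"unsupported format {format!r} (use 'svg' or 'png')")
    colors = dict(_BAND_COLORS)
    if band_colors:
        colors.update(band_colors)
    horizon = layout.design.horizon_days
    n_panels = len(layout.panels)
    heights = [max(p.n, 1) for p in layout.panels]
    if figsize is None:
        figsize = (10.0, max(4.0, 0.12 * sum(heights) + 0.6 * n_panels))
    fig, axes = plt.subplots(
        n_panels, 1, figsize=figsize, sharex=True,
        gridspec_kw={"height_ratios": heights},
    )
    if n_panels == 1:
        axes = [axes]
    denom = layout.denominator or 1
    for ax, panel in zip(axes, layout.panels):
        for name, (lo, hi) in layout.band_ranges.items():
            ax.axvspan(horizon - hi, horizon - lo, color=colors.get(name, "#dddddd"),
                       alpha=0.5, lw=0, zorder=0)
        for row in panel.rows:
            xs = [horizon - off for off in row.offsets]
            ax.plot(xs, [row.row_index] * len(xs), linestyle="none",
                    marker=marker, color="black", markersize=6, zorder=2)
        label = f"Stratum {panel.stratum}  n={panel.n} ({100.0 * panel.n / denom:.0f}%)"
        if panel.decision is not None and panel.n > 0:
            label += (f"  CW1: {panel.decision.verdict_cw1}"
                      f" / CW2: {panel.decision.verdict_cw2}")
        ax.set_title(label, loc="left", fontsize=9)
        ax.set_ylim(-0.8, max(panel.n - 1, 0) + 0.8)
        ax.invert_yaxis()
        ax.set_yticks([])
        ax.set_xlim(-1, horizon + 1)
    ticks = list(range(0, horizon + 1, max(horizon // 8, 1)))
    axes[-1].set_xticks([horizon - t for t in ticks])
    axes[-1].set_xticklabels([str(t) for t in ticks])
    axes[-1].set_xlabel("days pre-event (event at right)")
    fig.tight_layout()
    if path is None:
        return fig
    fig.savefig(path, format=format, dpi=dpi)
    plt.close(fig)
    return path


def export_layout(layout: PanelLayout, path) -> None:
    """Write the layout as TSV: stratum, row, subject_id, offsets (';'-joined).

    The export is byte-identical for identical inputs and is the surface
    used for regression testing instead of image comparison.
    """
    with open(path, "w") as fh:
        fh.write("stratum\trow\tsubject_id\toffsets\n")
        for panel in layout.panels:
            for row in panel.rows:
                offs = ";".join(str(o) for o in row.offsets)
                fh.write(f"{panel.stratum}\t{row.row_index}\t{row.subject_id}\t{offs}\n")


def parse_layout(path) -> dict[str, list[tuple[int, str, tuple[int, ...]]]]:
    """Re-read an exported layout TSV into {stratum: [(row, subject_id, offsets)]}."""
    out: dict[str, list[tuple[int, str, tuple[int, ...]]]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["stratum", "row", "subject_id", "offsets"]:
            raise ValueError(f"unexpected layout header: {header}")
        for line in fh:
            stratum, row, sid, offs = line.rstrip("\n").split("\t")
            offsets = tuple(int(o) for o in offs.split(";")) if offs else ()
            out.setdefault(stratum, []).append((int(row), sid, offsets))
    return out
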