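"""Segment-chaining crown chronology.

The reconstruction follows the standard histological bookkeeping for
enamel: starting at the dentine horn, a ~200 µm prism segment is traced;
the stria of Retzius at its outer end is an isochrone, so where it meets
the enamel–dentine junction (EDJ) a new ameloblast was being recruited
at that same moment — the next 200 µm segment starts there, and so on to
the cervix. Each segment's duration in days is its prism length divided
by the local mean daily secretion rate (DSR), itself the mean of
cross-striation run measurements (run length / number of daily
striations). Summing segment durations gives the crown formation time
(CFT); the neonatal line (NNL) splits it into crown initiation
(Ci, days before birth) and crown completion (Cc, days after birth),
and any accentuated line (AL) can be dated the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import Polyline
from .tracings import (
    ChronologyRecord,
    CrossStriationRun,
    StriaTrace,
    ToothSection,
)

DEFAULT_CHAIN_TOLERANCE_UM = 25.0   # tracing jitter allowance at 10x magnification
DSR_PLAUSIBILITY_BAND = (1.0, 8.0)  # µm/day; outside -> QC flag, not rejection

__all__ = [
    "SegmentChronology",
    "ChronologyResult",
    "ChainError",
    "local_dsr",
    "build_segment_chain",
    "crown_chronology",
    "locate_event_day",
    "event_ages_relative_to_birth",
    "round_days",
]


class ChainError(ValueError):
    """Raised when the prism-segment chain cannot be assembled."""


def round_days(value: float) -> int:
    """Round to integer days, half away from zero (report convention)."""
    return int(np.sign(value) * np.floor(abs(value) + 0.5))


@dataclass
class SegmentChronology:
    """One chained prism segment with its timing.

    ``days = length / local_dsr``; cumulative days are measured from
    crown initiation; EDJ arcs are µm along the EDJ from the dentine
    horn. Timing fields are NaN on the skeleton returned by
    :func:`build_segment_chain` until rates are attached.
    """

    index: int
    length: float                 # µm along the prism
    edj_start_arc: float          # µm along EDJ
    edj_end_arc: float
    path: Polyline = field(repr=False, default=None)
    local_dsr: float = float("nan")   # µm/day
    days: float = float("nan")
    cum_days_start: float = float("nan")
    cum_days_end: float = float("nan")


@dataclass
class ChronologyResult:
    """Day-resolved chronology of one crown."""

    section_id: str
    segments: list[SegmentChronology]
    cft: float                              # days, pre-rounding
    ci: Optional[float] = None              # days before birth
    cc: Optional[float] = None              # days after birth
    birth_cum_day: Optional[float] = None   # days since initiation
    event_ages: list[tuple[str, float]] = field(default_factory=list)  # rel. birth
    dsr_prenatal_mean: Optional[float] = None
    dsr_postnatal_mean: Optional[float] = None
    dsr_overall_mean: Optional[float] = None
    cft_is_minimum: bool = False            # worn dentine horn
    cft_excluded: bool = False              # from CFT group means
    cc_excluded: bool = False               # broken cervix / editorial
    qc_flags: list[str] = field(default_factory=list)

    @property
    def cft_rounded(self) -> int:
        return round_days(self.cft)

    def to_record(self, section: ToothSection, individual: str = "") -> ChronologyRecord:
        broken = section.flags.broken_cervix
        return ChronologyRecord(
            id=section.id,
            site=section.site,
            individual=individual or section.id,
            arch=section.arch,
            sex=section.sex,
            wear_stage=section.wear_stage,
            cft=None if broken else self.cft,
            ci=self.ci,
            cc=None if broken else self.cc,
            inner_dsr_mean=self.dsr_overall_mean,
            n_accentuated=sum(1 for s in section.striae if s.kind == "accentuated"),
            cft_ci_eligible=not (section.flags.worn_horn or broken),
            cc_excluded=broken or section.flags.exclude_cc,
        )


# ---------------------------------------------------------------------------


def local_dsr(runs_for_segment: Sequence[CrossStriationRun]) -> float:
    """Local mean daily secretion rate of one segment, µm/day.

    Each cross-striation run contributes run_length / n_striations; runs
    are averaged unweighted (each run is one local reading, regardless
    of how many striations it spans). A value outside the plausibility
    band [1, 8] µm/day triggers a warning but is returned as-is.
    """
    runs = list(runs_for_segment)
    if not runs:
        raise ChainError("segment has no DSR runs")
    value = float(np.mean([r.dsr for r in runs]))
    lo, hi = DSR_PLAUSIBILITY_BAND
    if not lo <= value <= hi:
        warnings.warn(f"local DSR {value:.2f} µm/day outside [{lo}, {hi}]", stacklevel=2)
    return value


def _oriented_path(prism) -> Polyline:
    """Prism path ordered EDJ -> enamel (flip if traced the other way)."""
    path = prism.path
    d0 = prism.start_on_edj.distance_to(Point2DFromArray(path.coords[0]))
    d1 = prism.start_on_edj.distance_to(Point2DFromArray(path.coords[-1]))
    return path if d0 <= d1 else path.reversed()


def Point2DFromArray(xy):
    from .geometry import Point2D

    return Point2D(float(xy[0]), float(xy[1]))


def _stria_edj_arc(stria: StriaTrace, edj: Polyline, tolerance: float):
    """EDJ arc position where a stria reaches the junction.

    Prefers a true geometric crossing; falls back to projecting the
    stria endpoint nearest the EDJ when the trace stops just short.
    Returns None if the stria stays farther than ``tolerance`` from the
    EDJ.
    """
    hits = edj.intersections_with(stria.path)
    if hits:
        return hits[-1][0] if len(hits) == 1 else max(h[0] for h in hits)
    ends = [Point2DFromArray(stria.path.coords[i]) for i in (0, -1)]
    dists = [edj.distance_to_point(p) for p in ends]
    k = int(np.argmin(dists))
    if dists[k] > tolerance:
        return None
    return edj.project(ends[k])


def build_segment_chain(
    section: ToothSection, tolerance: float = DEFAULT_CHAIN_TOLERANCE_UM
) -> list[SegmentChronology]:
    """Assemble the prism-segment chain and its EDJ arc positions.

    For every consecutive pair of segments, the terminal stria of the
    first must reach the EDJ within ``tolerance`` (µm of EDJ arc) of the
    next segment's starting point; a larger gap is an error naming the
    offending segment. EDJ arc positions must increase cusp -> cervix.
    The returned skeletons have geometry only; rates and days are
    attached by :func:`crown_chronology`.
    """
    if not section.prisms:
        raise ChainError("section has no prism segments")
    prisms = sorted(section.prisms, key=lambda p: p.index)
    striae = {s.id: s for s in section.striae}
    edj = section.edj

    starts = []
    for p in prisms:
        if edj.distance_to_point(p.start_on_edj) > tolerance:
            raise ChainError(
                f"segment {p.index}: start point is {edj.distance_to_point(p.start_on_edj):.1f} µm "
                f"from the EDJ (tolerance {tolerance} µm)"
            )
        starts.append(edj.project(p.start_on_edj))

    segments: list[SegmentChronology] = []
    for i, p in enumerate(prisms):
        if p.terminal_stria is not None:
            arc = _stria_edj_arc(striae[p.terminal_stria], edj, tolerance)
            if arc is None:
                raise ChainError(
                    f"segment {p.index}: terminal stria {p.terminal_stria!r} does not reach the EDJ"
                )
        else:
            if i != len(prisms) - 1:
                raise ChainError(f"segment {p.index}: missing terminal stria in mid-chain")
            arc = edj.arc_length  # cervix
        if i < len(prisms) - 1:
            gap = abs(arc - starts[i + 1])
            if gap > tolerance:
                raise ChainError(
                    f"segment {p.index}: terminal stria meets the EDJ {gap:.1f} µm from "
                    f"segment {prisms[i + 1].index}'s start (tolerance {tolerance} µm)"
                )
            end_arc = starts[i + 1]
        else:
            end_arc = arc
        segments.append(
            SegmentChronology(
                index=p.index,
                length=p.path.arc_length,
                edj_start_arc=starts[i],
                edj_end_arc=end_arc,
                path=_oriented_path(p),
            )
        )

    arcs = [s.edj_start_arc for s in segments] + [segments[-1].edj_end_arc]
    if np.any(np.diff(arcs) <= 0):
        raise ChainError("EDJ arc positions are not strictly increasing along the chain")
    return segments


def locate_event_day(segments: Sequence[SegmentChronology], stria: StriaTrace) -> tuple[float, list[str]]:
    """Date a stria: days since crown initiation, plus QC flags.

    The stria is intersected with each chained prism path; within the
    crossed segment the day is linearly interpolated in prism arc
    length: ``day = cum_start + (arc / length) * days``. With multiple
    crossings the one nearest the EDJ is used (flagged).
    """
    hits: list[tuple[float, SegmentChronology]] = []
    for seg in segments:
        for arc, _pt in seg.path.intersections_with(stria.path):
            hits.append((arc, seg))
    if not hits:
        raise ChainError(f"stria {stria.id!r} does not cross any chained prism segment")
    flags = []
    if len(hits) > 1:
        flags.append(f"multiple_intersections:{stria.id}")
    arc, seg = min(hits, key=lambda h: h[0])
    frac = min(arc / seg.length, 1.0)
    return seg.cum_days_start + frac * seg.days, flags


def crown_chronology(
    section: ToothSection, tolerance: float = DEFAULT_CHAIN_TOLERANCE_UM
) -> ChronologyResult:
    """Full day-resolved chronology of one section.

    Requires at least one cross-striation run per chained segment. The
    NNL, if present and datable, splits CFT into Ci and Cc (Ci + Cc =
    CFT exactly, before rounding). Worn-horn sections yield minimum CFT
    / Ci estimates flagged as excluded from group means; broken-cervix
    sections have CFT and Cc excluded.
    """
    segments = build_segment_chain(section, tolerance=tolerance)
    qc: list[str] = []
    if section.flags.worn_horn:
        qc.append("worn_start")

    t = 0.0
    for seg in segments:
        runs = section.runs_for_segment(seg.index)
        if not runs:
            raise ChainError(f"segment {seg.index} has no DSR runs")
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            seg.local_dsr = local_dsr(runs)
        if wlist:
            qc.append(f"dsr_out_of_band:{seg.index}")
        seg.days = seg.length / seg.local_dsr
        seg.cum_days_start = t
        t += seg.days
        seg.cum_days_end = t
    cft = t

    result = ChronologyResult(
        section_id=section.id,
        segments=segments,
        cft=cft,
        cft_is_minimum=section.flags.worn_horn,
        cft_excluded=section.flags.worn_horn or section.flags.broken_cervix,
        cc_excluded=section.flags.broken_cervix or section.flags.exclude_cc,
        qc_flags=qc,
    )

    nnl = section.neonatal_line
    if nnl is None:
        qc.append("no_neonatal_line")
    else:
        try:
            birth, flags = locate_event_day(segments, nnl)
        except ChainError:
            qc.append("neonatal_line_not_datable")
        else:
            qc.extend(flags)
            result.birth_cum_day = birth
            result.ci = birth
            result.cc = cft - birth

    for s in section.striae:
        if s.kind != "accentuated":
            continue
        try:
            day, flags = locate_event_day(segments, s)
        except ChainError:
            qc.append(f"accentuated_not_datable:{s.id}")
            continue
        qc.extend(flags)
        ref = result.birth_cum_day if result.birth_cum_day is not None else 0.0
        result.event_ages.append((s.id, day - ref))
    if result.birth_cum_day is None and result.event_ages:
        qc.append("event_ages_since_initiation")

    _attach_dsr_means(section, result)
    return result


def _attach_dsr_means(section: ToothSection, result: ChronologyResult) -> None:
    """Pre/postnatal/overall mean DSR over all runs, split at the NNL.

    A run inherits its segment's time span; a segment straddling birth
    is assigned by its midpoint.
    """
    by_index = {s.index: s for s in result.segments}
    pre, post, all_ = [], [], []
    for run in section.runs:
        seg = by_index.get(run.segment_index)
        if seg is None:
            continue
        all_.append(run.dsr)
        if result.birth_cum_day is not None:
            mid = 0.5 * (seg.cum_days_start + seg.cum_days_end)
            (pre if mid < result.birth_cum_day else post).append(run.dsr)
    if all_:
        result.dsr_overall_mean = float(np.mean(all_))
    if pre:
        result.dsr_prenatal_mean = float(np.mean(pre))
    if post:
        result.dsr_postnatal_mean = float(np.mean(post))


def event_ages_relative_to_birth(result: ChronologyResult) -> list[tuple[str, float]]:
    """Accentuated-line ages in days relative to birth (negative = prenatal).

    If birth is unknown the ages are relative to crown initiation and
    the result carries the ``event_ages_since_initiation`` QC flag.
    """
    return list(result.event_ages)
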