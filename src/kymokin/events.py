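"""Kinetic points of interest on boundary transition-time curves.

Under the first-bound-time convention used throughout this package, a
nucleation (the first tropomyosin binding an unbound stretch) is a local
MINIMUM of tau(x) during association — the nucleation pixel binds earliest
and binding spreads outward — and a meeting point (two same-side strands
growing toward each other and stopping) is a local MAXIMUM.  During
dissociation, with tau(x) the last bound frame, a dissociation initiation
point (DIP, first unbinding of a domain) is a local minimum / domain edge
and a dissociation end point (DEP, the last tropomyosin of a shrinking
domain to leave) is a local maximum.

Events detected on the inner (single<->double) boundary are nucleations or
meetings of the second filament side; extrema that pair up into candidate
crossings (strands elongating past each other on opposite sides) are
excluded from the event lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks

from .boundaries import BoundarySet, Segment, find_candidate_crossings


@dataclass(frozen=True)
class Event:
    position: int  # pixel
    time: float  # frames (absolute index)
    segment_id: int
    kind: str  # nucleation | meeting | dip | dep | user
    label: str = ""


@dataclass
class EventSet:
    """Detected events plus optional user-marked points of interest."""

    nucleations: List[Event] = field(default_factory=list)
    meetings: List[Event] = field(default_factory=list)
    dips: List[Event] = field(default_factory=list)
    deps: List[Event] = field(default_factory=list)
    user_marks: List[Event] = field(default_factory=list)
    left_censored_segments: List[int] = field(default_factory=list)

    def all_events(self) -> List[Event]:
        return self.nucleations + self.meetings + self.dips + self.deps


@dataclass(frozen=True)
class ExtremaSettings:
    """Robustness parameters for extrema search on tau(x).

    tau is smoothed with a moving median of ``smoothing_window`` positions
    before the search; extrema need a prominence of at least
    ``min_prominence`` frames and a spacing of at least ``min_separation``
    positions.  Raw tau is never modified.
    """

    smoothing_window: int = 3
    min_prominence: float = 2.0
    min_separation: int = 2
    crossing_pos_tol: int = 2
    crossing_time_tol: float = 3.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        if self.min_prominence < 0 or self.min_separation < 0:
            raise ValueError("prominence and separation must be >= 0")


def _smooth(tau: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return tau
    return ndimage.median_filter(tau, size=window, mode="nearest")


def _segment_extrema(
    seg: Segment, sense: str, s: ExtremaSettings
) -> List[Tuple[int, float]]:
    """(position, time) of interior extrema of a segment's tau polyline."""
    verts = seg.vertices
    if len(verts) < 3:
        return []
    tau = _smooth(verts[:, 1], s.smoothing_window)
    sig = tau if sense == "max" else -tau
    peaks, _ = find_peaks(
        sig,
        prominence=s.min_prominence if s.min_prominence > 0 else None,
        distance=max(s.min_separation, 1),
        plateau_size=1,
    )
    out = []
    for p in peaks:
        # report the raw (unsmoothed) extremal vertex nearest the smoothed peak
        lo = max(p - s.smoothing_window // 2, 0)
        hi = min(p + s.smoothing_window // 2 + 1, len(verts))
        local = verts[lo:hi, 1]
        j = lo + (int(np.argmax(local)) if sense == "max" else int(np.argmin(local)))
        out.append((int(verts[j, 0]), float(verts[j, 1])))
    return out


def _near_crossing(
    pos: int, t: float, crossings, pos_tol: int, time_tol: float
) -> bool:
    return any(
        abs(pos - c.position) <= pos_tol and abs(t - c.time) <= time_tol
        for c in crossings
    )


def detect_nucleations(b: BoundarySet, s: ExtremaSettings = ExtremaSettings()) -> List[Event]:
    """Nucleation points: extrema of tau(x) where binding occurs earliest locally.

    Searched on every association segment (both boundary levels — an inner-
    boundary minimum is a nucleation on the second filament side), excluding
    extrema that participate in candidate crossings.  A strand already bound
    at the first frame of the phase has no detectable nucleation and its
    segment is flagged left-censored by :func:`detect_all`.
    """
    if b.phase != "association":
        raise ValueError("nucleations are association-phase events")
    crossings = find_candidate_crossings(b, s.crossing_pos_tol, s.crossing_time_tol)
    events = []
    for seg in b.segments:
        for pos, t in _segment_extrema(seg, "min", s):
            if seg.level == 2 and _near_crossing(
                pos, t, crossings, s.crossing_pos_tol, s.crossing_time_tol
            ):
                continue  # inner-boundary minimum explained by a crossing
            events.append(Event(pos, t, seg.seg_id, "nucleation"))
    events.sort(key=lambda e: (e.time, e.position))
    return events


def detect_meetings(b: BoundarySet, s: ExtremaSettings = ExtremaSettings()) -> List[Event]:
    """Meeting points: extrema of tau(x) with the latest local binding time
    between two nucleations on the same side, crossings excluded."""
    if b.phase != "association":
        raise ValueError("meetings are association-phase events")
    crossings = find_candidate_crossings(b, s.crossing_pos_tol, s.crossing_time_tol)
    events = []
    for seg in b.segments:
        for pos, t in _segment_extrema(seg, "max", s):
            if seg.level == 1 and _near_crossing(
                pos, t, crossings, s.crossing_pos_tol, s.crossing_time_tol
            ):
                continue  # outer-boundary maximum explained by a crossing
            events.append(Event(pos, t, seg.seg_id, "meeting"))
    events.sort(key=lambda e: (e.time, e.position))
    return events


def detect_dissociation_points(
    b: BoundarySet, s: ExtremaSettings = ExtremaSettings()
) -> Tuple[List[Event], List[Event]]:
    """DIPs and DEPs on a dissociation-phase BoundarySet.

    DIP: locally earliest unbinding — interior local minima of the last-bound
    curve plus the terminal vertices of each segment (the original domain
    edges, which unbind first).  DEP: the vanishing point of a shrinking
    domain — interior local maxima; a plateau still bound in the final
    recorded frame is right-censored and yields no DEP.
    """
    if b.phase != "dissociation":
        raise ValueError("DIP/DEP are dissociation-phase events")
    start, stop = b.frame_range
    last_frame = stop - 1
    dips: List[Event] = []
    deps: List[Event] = []
    for seg in b.segments:
        verts = seg.vertices
        for pos, t in _segment_extrema(seg, "min", s):
            dips.append(Event(pos, t, seg.seg_id, "dip"))
        for end_idx in (0, len(verts) - 1):
            pos, t = int(verts[end_idx, 0]), float(verts[end_idx, 1])
            dips.append(Event(pos, t, seg.seg_id, "dip"))
        for pos, t in _segment_extrema(seg, "max", s):
            if t >= last_frame:
                continue  # still bound at the end of the recording: censored
            deps.append(Event(pos, t, seg.seg_id, "dep"))
    dips.sort(key=lambda e: (e.time, e.position))
    deps.sort(key=lambda e: (e.time, e.position))
    return dips, deps


def detect_all(b: BoundarySet, s: ExtremaSettings = ExtremaSettings()) -> EventSet:
    """Run the detections appropriate for the BoundarySet's phase."""
    es = EventSet()
    if b.phase == "association":
        es.nucleations = detect_nucleations(b, s)
        es.meetings = detect_meetings(b, s)
        start = b.frame_range[0]
        es.left_censored_segments = [
            seg.seg_id
            for seg in b.segments
            if len(seg.vertices) and np.min(seg.vertices[:, 1]) <= start
        ]
    else:
        es.dips, es.deps = detect_dissociation_points(b, s)
    return es


MAX_GAP_MONOMERS = 6  # one dimer spans 7 actin subunits, so an unresolvable
ACTIN_MONOMER_RISE_NM = 2.75  # gap is at most 6 monomers long


@dataclass(frozen=True)
class GapAnnotation:
    """Join-vs-gap annotation for a meeting point.

    Two strands meeting in register join seamlessly; out of register they
    leave an undecorated gap of 1-6 actin monomers, far below the optical
    resolution, so the kymograph cannot distinguish the two outcomes.
    """

    max_gap_monomers: int
    max_gap_nm: float
    pixel_size_nm: float
    sub_pixel: bool  # True when the largest possible gap is < 1 pixel
    resolvable: bool  # always False at realistic pixel sizes


def classify_meeting_gap(event: Event, pixel_size_nm: float) -> GapAnnotation:
    """Annotate a meeting point with the maximum unresolvable gap length."""
    if event.kind != "meeting":
        raise ValueError("classify_meeting_gap expects a meeting event")
    max_gap_nm = MAX_GAP_MONOMERS * ACTIN_MONOMER_RISE_NM
    return GapAnnotation(
        max_gap_monomers=MAX_GAP_MONOMERS,
        max_gap_nm=max_gap_nm,
        pixel_size_nm=pixel_size_nm,
        sub_pixel=max_gap_nm < pixel_size_nm,
        resolvable=max_gap_nm >= pixel_size_nm,
    )


def check_alternation(b: BoundarySet, events: EventSet) -> bool:
    """Nucleations and meetings alternate along each boundary segment.

    Two adjacent same-kind events are only admissible when the boundary
    curve makes an opposite-sense excursion between them (the separating
    extremum then belongs to the other boundary level, was filtered by the
    prominence settings, or is a crossing candidate): two nucleations
    (minima) must be separated by a rise of tau above both, two meetings
    (maxima) by a dip below both.  Returns False when same-kind events sit
    adjacent with no intervening excursion — a detection bookkeeping error.
    """
    seg_by_id = {s.seg_id: s for s in b.segments}
    by_seg: dict = {}
    for e in events.nucleations + events.meetings:
        by_seg.setdefault(e.segment_id, []).append(e)
    for seg_id, seg_events in by_seg.items():
        seg = seg_by_id.get(seg_id)
        if seg is None:
            return False
        pos = seg.vertices[:, 0]
        tau = seg.vertices[:, 1]
        seg_events.sort(key=lambda e: e.position)
        for a, c in zip(seg_events, seg_events[1:]):
            if a.kind != c.kind:
                continue
            inside = (pos > a.position) & (pos < c.position)
            if not inside.any():
                return False
            bound = max(a.time, c.time) if a.kind == "nucleation" else min(a.time, c.time)
            if a.kind == "nucleation":
                if tau[inside].max() <= bound:
                    return False
            else:
                if tau[inside].min() >= bound:
                    return False
    return True
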