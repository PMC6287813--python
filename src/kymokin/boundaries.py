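"""Boundary detection, validation and editing on kymographs.

A three-level kymograph (background / single-bound / double-bound) is
binarised at two thresholds.  Each binary image is cleaned by a 2-D median
filter followed by morphological erosion, hole in-fill and re-dilation, and
the transition-time curve tau(x) is read off per position: the first bound
frame during association, the last bound frame during dissociation.

The per-pixel double-step fit (two intensity transitions of identical
magnitude) provides an independent cross-validation of the thresholded
boundaries: on clean data the fitted transition times coincide with tau.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.morphology import disk

from .kymo import Kymograph

# ----------------------------------------------------------------------- settings


@dataclass(frozen=True)
class ThresholdSettings:
    """Binarisation and morphology settings for boundary detection.

    ``low_threshold`` separates background from single-bound intensity,
    ``high_threshold`` single- from double-bound.  ``median_window`` is the
    (position, frame) size of the 2-D median filter; window (1, 1) and a
    structuring element of size 0 disable the respective cleanup step, which
    is appropriate for noiseless data.
    """

    low_threshold: float
    high_threshold: float
    median_window: Tuple[int, int] = (3, 3)
    structuring_element: Tuple[str, int] = ("disk", 2)  # (shape, size); size 0 = off
    auto: bool = False

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be < high_threshold")
        if any(w < 1 or w % 2 == 0 for w in self.median_window):
            raise ValueError("median_window dims must be odd and >= 1")
        shape, size = self.structuring_element
        if shape not in ("disk", "rect"):
            raise ValueError("structuring_element shape must be 'disk' or 'rect'")
        if size < 0:
            raise ValueError("structuring_element size must be >= 0")


# ----------------------------------------------------------------------- segments


@dataclass
class Segment:
    """An ordered polyline of (position, time) boundary vertices."""

    seg_id: int
    vertices: np.ndarray  # (N, 2): position, time (absolute frames)
    level: int  # 1 = background<->single, 2 = single<->double
    side: str = "unassigned"  # 'A' | 'B' | 'unassigned'

    def copy(self) -> "Segment":
        return Segment(self.seg_id, self.vertices.copy(), self.level, self.side)

    @property
    def start(self) -> np.ndarray:
        return self.vertices[0]

    @property
    def end(self) -> np.ndarray:
        return self.vertices[-1]


@dataclass
class BoundarySet:
    """Detected transition-time curves plus editable polyline segments.

    ``tau_outer``/``tau_inner`` are per-position transition times in absolute
    frame indices (NaN where undefined).  ``segments`` start as maximal
    connected runs of defined tau and can be cut/joined/relabelled through
    :func:`edit_boundaries`; ``edit_log`` replayed on the raw detection
    reproduces the current segments exactly.
    """

    tau_outer: np.ndarray
    tau_inner: np.ndarray
    phase: str  # 'association' | 'dissociation'
    frame_range: Tuple[int, int]  # [start, stop) absolute frames of the phase
    segments: List[Segment] = field(default_factory=list)
    edit_log: List[dict] = field(default_factory=list)
    masked_ranges: List[Tuple[int, int]] = field(default_factory=list)
    raw_segments: List[Segment] = field(default_factory=list)
    masks: dict = field(default_factory=dict)  # level -> cleaned bool mask (pos, phase frame)
    meta: dict = field(default_factory=dict)

    def segment(self, seg_id: int) -> Segment:
        for s in self.segments:
            if s.seg_id == seg_id:
                return s
        raise KeyError(f"no segment with id {seg_id}")

    def validate(self) -> None:
        both = np.isfinite(self.tau_outer) & np.isfinite(self.tau_inner)
        if self.phase == "association":
            if np.any(self.tau_outer[both] > self.tau_inner[both]):
                raise AssertionError("tau_outer must precede tau_inner during association")
        else:
            if np.any(self.tau_outer[both] < self.tau_inner[both]):
                raise AssertionError("tau_outer must follow tau_inner during dissociation")


# ---------------------------------------------------------------------- detection


def _structuring_array(spec: Tuple[str, int]) -> Optional[np.ndarray]:
    shape, size = spec
    if size == 0:
        return None
    if shape == "disk":
        return disk(size).astype(bool)
    return np.ones((size, size), dtype=bool)


def _clean_mask(mask: np.ndarray, settings: ThresholdSettings) -> np.ndarray:
    out = mask
    if settings.median_window != (1, 1):
        out = ndimage.median_filter(out.astype(np.uint8), size=settings.median_window) > 0
    selem = _structuring_array(settings.structuring_element)
    if selem is not None:
        out = ndimage.binary_erosion(out, structure=selem)
        out = ndimage.binary_fill_holes(out)
        out = ndimage.binary_dilation(out, structure=selem)
    else:
        out = ndimage.binary_fill_holes(out)
    return out


def _tau_from_mask(mask: np.ndarray, phase: str, frame_start: int) -> np.ndarray:
    """First (association) or last (dissociation) on-frame per position, absolute."""
    n_pos, n_t = mask.shape
    tau = np.full(n_pos, np.nan)
    on = mask.any(axis=1)
    if phase == "association":
        tau[on] = mask[on].argmax(axis=1) + frame_start
    else:
        tau[on] = n_t - 1 - mask[on, ::-1].argmax(axis=1) + frame_start
    return tau


def _segments_from_tau(tau: np.ndarray, level: int, start_id: int) -> List[Segment]:
    segs = []
    defined = np.isfinite(tau)
    idx = np.nonzero(defined)[0]
    if idx.size == 0:
        return segs
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [idx.size - 1]])
    sid = start_id
    for a, b in zip(run_starts, run_ends):
        xs = idx[a : b + 1]
        verts = np.column_stack([xs.astype(float), tau[xs]])
        segs.append(Segment(seg_id=sid, vertices=verts, level=level))
        sid += 1
    return segs


def detect_boundaries(
    kymo: Kymograph,
    settings: ThresholdSettings,
    phase: str = "association",
) -> BoundarySet:
    """Detect the two intensity-level boundaries in one acquisition phase.

    For each threshold the kymograph is binarised, cleaned (median filter,
    erosion, hole fill, dilation) and reduced to a transition-time curve
    tau(x).  Segments are initialised as maximal connected runs of defined
    tau with side label 'unassigned'.
    """
    start, stop = kymo.phase_frames(phase)
    sub = kymo.intensity[:, start:stop]
    if not np.any(sub >= settings.low_threshold):
        warnings.warn("no pixel above low_threshold; returning empty BoundarySet")
        n = kymo.n_positions
        return BoundarySet(
            tau_outer=np.full(n, np.nan),
            tau_inner=np.full(n, np.nan),
            phase=phase,
            frame_range=(start, stop),
        )
    taus = {}
    masks = {}
    for level, thr in ((1, settings.low_threshold), (2, settings.high_threshold)):
        cleaned = _clean_mask(sub >= thr, settings)
        masks[level] = cleaned
        taus[level] = _tau_from_mask(cleaned, phase, start)
    segs = _segments_from_tau(taus[1], level=1, start_id=0)
    segs += _segments_from_tau(taus[2], level=2, start_id=len(segs))
    b = BoundarySet(
        tau_outer=taus[1],
        tau_inner=taus[2],
        phase=phase,
        frame_range=(start, stop),
        segments=segs,
        raw_segments=[s.copy() for s in segs],
        masks=masks,
    )
    b.validate()
    return b


def auto_thresholds(kymo: Kymograph) -> Tuple[float, float]:
    """Starting thresholds from a 3-class minimum-within-class-variance split.

    Intended as initial values for user adjustment.  On a two-level
    kymograph the high cut is degenerate; a warning is issued and the high
    threshold is placed above the brightest pixel.
    """
    values = kymo.intensity.ravel()
    distinct = np.unique(values)
    if distinct.size < 2:
        raise ValueError("degenerate histogram: < 2 distinct intensity values")
    try:
        low, high = threshold_multiotsu(values, classes=3)
    except ValueError:
        low = float(threshold_otsu(values))
        high = float(distinct[-1]) + 1.0
        warnings.warn("high threshold degenerate (two-level kymograph)")
        return low, high
    if not np.any(values >= high):
        warnings.warn("high threshold degenerate (no pixels above high cut)")
    return float(low), float(high)


# ------------------------------------------------------------------ step fitting


@dataclass(frozen=True)
class StepFit:
    """Least-squares double-step fit to one pixel's intensity profile.

    Model: baseline + magnitude*[t >= t1] + magnitude*[t >= t2] for
    association (steps subtracted for dissociation), with t1 <= t2 and a
    magnitude shared by both transitions.
    """

    baseline: float
    magnitude: float
    t1: int
    t2: int
    rss: float


def fit_double_step(profile: Sequence[float], phase: str = "association") -> StepFit:
    """Globally optimal integer-time double-step fit to an intensity profile.

    All (t1, t2) pairs with 0 <= t1 <= t2 < T are searched; for each pair the
    baseline and shared magnitude have closed-form least-squares solutions.
    Ties are broken by smallest t1 then smallest t2.  Times are indices into
    ``profile``.
    """
    y = np.asarray(profile, dtype=float)
    T = y.size
    if T < 3:
        raise ValueError("profile must have length >= 3")
    if phase not in ("association", "dissociation"):
        raise ValueError(f"unknown phase {phase!r}")
    cy = np.concatenate([[0.0], np.cumsum(y)])
    Sy = cy[-1]
    Syy = float(np.dot(y, y))
    i = np.arange(T)
    I, J = np.meshgrid(i, i, indexing="ij")  # I = t1, J = t2
    valid = I <= J
    Sx = (T - I) + (T - J)
    Sxx = (J - I) + 4.0 * (T - J)
    Sxy = (Sy - cy[I]) + (Sy - cy[J])
    den = T * Sxx - Sx.astype(float) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(den != 0, (T * Sxy - Sx * Sy) / np.where(den != 0, den, 1.0), 0.0)
    b = (Sy - m * Sx) / T
    rss = Syy + T * b**2 + m**2 * Sxx - 2 * b * Sy - 2 * m * Sxy + 2 * b * m * Sx
    rss = np.where(valid, rss, np.inf)
    rss = np.maximum(rss, 0.0)
    best = rss.min()
    tol = 1e-9 * (1.0 + Syy)
    ties = np.argwhere(rss <= best + tol)
    t1, t2 = min(map(tuple, ties))  # lexicographic: smallest t1 then t2
    slope = float(m[t1, t2])
    magnitude = slope if phase == "association" else -slope
    return StepFit(
        baseline=float(b[t1, t2]),
        magnitude=magnitude,
        t1=int(t1),
        t2=int(t2),
        rss=float(rss[t1, t2]),
    )


# ----------------------------------------------------------------- region stats


@dataclass(frozen=True)
class RegionStats:
    """Mean intensities of the three boundary-defined regions and their steps.

    The two transition magnitudes are NOT constrained to be equal here (in
    contrast to the double-step fit); ``percent_difference`` is
    |step1 - step2| / mean(step1, step2) * 100.
    """

    mean_background: float
    mean_mid: float
    mean_high: float
    step1: float
    step2: float
    percent_difference: float
    empty_regions: Tuple[str, ...] = ()


def region_stats(kymo: Kymograph, b: BoundarySet) -> RegionStats:
    """Classify every (position, frame) of the phase by its relation to tau1/tau2."""
    if not np.any(np.isfinite(b.tau_outer)):
        raise ValueError("boundaries undefined at every position")
    start, stop = b.frame_range
    sub = kymo.intensity[:, start:stop]
    n_pos, n_t = sub.shape
    frames = np.arange(start, stop)[None, :]
    t1 = b.tau_outer[:, None]
    t2 = b.tau_inner[:, None]
    if b.phase == "association":
        bg = np.where(np.isfinite(t1), frames < t1, True)
        high = np.isfinite(t2) & (frames >= t2)
    else:  # last-bound convention: bound until tau, then background
        bg = np.where(np.isfinite(t1), frames > t1, True)
        high = np.isfinite(t2) & (frames <= t2)
    mid = ~bg & ~high
    means = {}
    empty = []
    for name, mask in (("background", bg), ("mid", mid), ("high", high)):
        if mask.any():
            means[name] = float(sub[mask].mean())
        else:
            means[name] = float("nan")
            empty.append(name)
    step1 = means["mid"] - means["background"]
    step2 = means["high"] - means["mid"]
    denom = 0.5 * (step1 + step2)
    pct = abs(step1 - step2) / denom * 100.0 if denom and np.isfinite(denom) else float("nan")
    return RegionStats(
        mean_background=means["background"],
        mean_mid=means["mid"],
        mean_high=means["high"],
        step1=step1,
        step2=step2,
        percent_difference=pct,
        empty_regions=tuple(empty),
    )


# -------------------------------------------------------------------- crossings


@dataclass(frozen=True)
class Crossing:
    """A candidate point where strands on opposite filament sides elongate past
    each other, scored by gradient continuity across the point."""

    position: int
    time: float
    score: float


def _extrema_of_tau(tau: np.ndarray, sense: str) -> List[int]:
    """Interior local extrema positions of a tau curve (NaN-aware)."""
    out: List[int] = []
    defined = np.isfinite(tau)
    idx = np.nonzero(defined)[0]
    if idx.size == 0:
        return out
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for a, bnd in zip(starts, ends):
        xs = idx[a : bnd + 1]
        if xs.size < 3:
            continue
        vals = tau[xs]
        sig = vals if sense == "max" else -vals
        peaks, _ = find_peaks(sig, plateau_size=1)
        out.extend(int(xs[p]) for p in peaks)
    return out


def _local_slope(tau: np.ndarray, x: int, direction: int, window: int = 3) -> float:
    """Slope (frames/pixel) of tau on one side of x; NaN if insufficient data."""
    if direction > 0:
        xs = np.arange(x, min(x + window + 1, tau.size))
    else:
        xs = np.arange(max(x - window, 0), x + 1)
    xs = xs[np.isfinite(tau[xs])]
    if xs.size < 2:
        return float("nan")
    return float(np.polyfit(xs, tau[xs], 1)[0])


def find_candidate_crossings(
    b: BoundarySet,
    pos_tol: int = 2,
    time_tol: float = 3.0,
    slope_window: int = 3,
) -> List[Crossing]:
    """Locate opposite-facing "V" pairs: an extremum of tau_outer coinciding
    with an opposite-sense extremum of tau_inner.

    Under the first-bound-time convention a crossing during association is a
    local MAXIMUM of tau_outer meeting a local MINIMUM of tau_inner (the two
    strand edges continue through each other on opposite filament sides).
    Candidates are ranked by similarity of the tau slopes either side of the
    point: a crossed boundary continues with a similar gradient.
    """
    if not (np.any(np.isfinite(b.tau_outer)) and np.any(np.isfinite(b.tau_inner))):
        return []
    if b.phase == "association":
        outer_ext = _extrema_of_tau(b.tau_outer, "max")
        inner_ext = _extrema_of_tau(b.tau_inner, "min")
    else:
        outer_ext = _extrema_of_tau(b.tau_outer, "min")
        inner_ext = _extrema_of_tau(b.tau_inner, "max")
    out: List[Crossing] = []
    for xo in outer_ext:
        for xi in inner_ext:
            if abs(xo - xi) > pos_tol:
                continue
            if abs(b.tau_outer[xo] - b.tau_inner[xi]) > time_tol:
                continue
            xc = (xo + xi) // 2
            s_out_l = _local_slope(b.tau_outer, xo, -1, slope_window)
            s_out_r = _local_slope(b.tau_outer, xo, +1, slope_window)
            s_in_l = _local_slope(b.tau_inner, xi, -1, slope_window)
            s_in_r = _local_slope(b.tau_inner, xi, +1, slope_window)
            # continuity: outer-left should continue as inner-right and vice versa
            mismatch = 0.0
            n_terms = 0
            for a_, b_ in ((s_out_l, s_in_r), (s_in_l, s_out_r)):
                if np.isfinite(a_) and np.isfinite(b_):
                    mismatch += abs(a_ - b_)
                    n_terms += 1
            score = 1.0 / (1.0 + mismatch / max(n_terms, 1)) if n_terms else 0.0
            t_c = 0.5 * (b.tau_outer[xo] + b.tau_inner[xi])
            out.append(Crossing(position=int(xc), time=float(t_c), score=score))
    out.sort(key=lambda c: (-c.score, c.position))
    return out


# ---------------------------------------------------------------------- editing


def _in_masked(pos: float, masked: List[Tuple[int, int]]) -> bool:
    return any(lo <= pos <= hi for lo, hi in masked)


def _apply_edit(
    segments: List[Segment],
    masked: List[Tuple[int, int]],
    op: dict,
    next_id: List[int],
    join_tol: float,
) -> None:
    kind = op["op"]
    if kind == "cut":
        seg = _get(segments, op["segment"])
        v = int(op["vertex"])
        if not (0 < v < len(seg.vertices) - 1):
            raise ValueError("cut vertex must be interior")
        if _in_masked(seg.vertices[v, 0], masked):
            raise ValueError("cannot edit a masked region")
        a = Segment(next_id[0], seg.vertices[: v + 1].copy(), seg.level, seg.side)
        bseg = Segment(next_id[0] + 1, seg.vertices[v:].copy(), seg.level, seg.side)
        next_id[0] += 2
        segments.remove(seg)
        segments.extend([a, bseg])
    elif kind == "join":
        (id_a, end_a), (id_b, end_b) = op["a"], op["b"]
        sa, sb = _get(segments, id_a), _get(segments, id_b)
        va = sa.vertices if end_a == "end" else sa.vertices[::-1]
        vb = sb.vertices if end_b == "start" else sb.vertices[::-1]
        gap = np.abs(va[-1] - vb[0])
        if gap.max() > join_tol:
            raise ValueError(
                f"dangling join: endpoints differ by {tuple(gap)} (tolerance {join_tol})"
            )
        if _in_masked(va[-1, 0], masked) or _in_masked(vb[0, 0], masked):
            raise ValueError("cannot edit a masked region")
        sides = {sa.side, sb.side} - {"unassigned"}
        if len(sides) > 1:
            raise ValueError("cannot join segments with conflicting side labels")
        side = sides.pop() if sides else "unassigned"
        # drop duplicated shared vertex if the ends coincide exactly
        if np.array_equal(va[-1], vb[0]):
            verts = np.vstack([va, vb[1:]])
        else:
            verts = np.vstack([va, vb])
        joined = Segment(next_id[0], verts, sa.level, side)
        next_id[0] += 1
        segments.remove(sa)
        segments.remove(sb)
        segments.append(joined)
    elif kind == "delete":
        segments.remove(_get(segments, op["segment"]))
    elif kind == "assign_side":
        side = op["side"]
        if side not in ("A", "B", "unassigned"):
            raise ValueError(f"invalid side {side!r}")
        _get(segments, op["segment"]).side = side
    elif kind == "mask_artifact":
        lo, hi = op["pos_range"]
        masked.append((int(lo), int(hi)))
        new_segments: List[Segment] = []
        for seg in segments:
            keep = ~((seg.vertices[:, 0] >= lo) & (seg.vertices[:, 0] <= hi))
            if keep.all():
                new_segments.append(seg)
                continue
            # split the surviving vertex runs into new segments
            runs = _bool_runs(keep)
            for a, bnd in runs:
                if bnd - a + 1 >= 2:
                    new_segments.append(
                        Segment(next_id[0], seg.vertices[a : bnd + 1].copy(), seg.level, seg.side)
                    )
                    next_id[0] += 1
        segments[:] = new_segments
    else:
        raise ValueError(f"unknown edit op {kind!r}")


def _bool_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b])) for a, b in zip(starts, ends)]


def _get(segments: List[Segment], seg_id: int) -> Segment:
    for s in segments:
        if s.seg_id == seg_id:
            return s
    raise KeyError(f"no segment with id {seg_id}")


def edit_boundaries(
    b: BoundarySet, ops: Sequence[dict], join_tol: float = 5.0
) -> BoundarySet:
    """Apply scripted edits (cut / join / delete / assign_side / mask_artifact).

    Returns a new BoundarySet; the input is unchanged.  The applied operations
    are appended to ``edit_log`` so that replaying the full log on the raw
    detection reproduces the result exactly (see :func:`replay_edits`).
    """
    out = BoundarySet(
        tau_outer=b.tau_outer.copy(),
        tau_inner=b.tau_inner.copy(),
        phase=b.phase,
        frame_range=b.frame_range,
        segments=[s.copy() for s in b.segments],
        edit_log=list(copy.deepcopy(b.edit_log)),
        masked_ranges=list(b.masked_ranges),
        raw_segments=[s.copy() for s in b.raw_segments],
        masks=b.masks,
        meta=dict(b.meta),
    )
    next_id = [max((s.seg_id for s in out.segments + out.raw_segments), default=-1) + 1]
    for op in ops:
        _apply_edit(out.segments, out.masked_ranges, copy.deepcopy(op), next_id, join_tol)
        out.edit_log.append(copy.deepcopy(op))
    for lo, hi in out.masked_ranges:
        out.tau_outer[lo : hi + 1] = np.nan
        out.tau_inner[lo : hi + 1] = np.nan
    return out


def replay_edits(b: BoundarySet, join_tol: float = 5.0) -> BoundarySet:
    """Re-apply ``b.edit_log`` to the raw detection; must reproduce ``b``."""
    fresh = BoundarySet(
        tau_outer=_raw_tau(b, 1),
        tau_inner=_raw_tau(b, 2),
        phase=b.phase,
        frame_range=b.frame_range,
        segments=[s.copy() for s in b.raw_segments],
        raw_segments=[s.copy() for s in b.raw_segments],
        masks=b.masks,
        meta=dict(b.meta),
    )
    return edit_boundaries(fresh, b.edit_log, join_tol=join_tol)


def _raw_tau(b: BoundarySet, level: int) -> np.ndarray:
    n = b.tau_outer.size
    tau = np.full(n, np.nan)
    for s in b.raw_segments:
        if s.level == level:
            tau[s.vertices[:, 0].astype(int)] = s.vertices[:, 1]
    return tau
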