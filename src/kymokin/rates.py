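"""Elongation / shrinkage rate estimation and the pixelation-limited cutoff.

Rates are the gradients of boundary transition-time curves: a linear
least-squares fit of boundary position versus time between a nucleation
point and its neighbouring end points (meeting, crossing cut, filament end
or phase end).  Because the camera pixelates the filament and the PSF blurs
it, measured rates have a floor: for actual rates A below a cutoff R_cutoff
the measured rate M plateaus at the cutoff,

    M = R_cutoff + (A - R_cutoff) * H(A - R_cutoff),

with H the Heaviside function.  The cutoff is calibrated by simulating
movies of filaments growing at known rates and pushing them through the
same kymograph -> boundary -> segment-fit pipeline as experimental data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .boundaries import BoundarySet, Segment, ThresholdSettings, detect_boundaries
from .events import Event, EventSet
from .kymo import extract_kymograph
from .stack import ImageStack

# ------------------------------------------------------------------------ types


@dataclass(frozen=True)
class RateRecord:
    """One fitted boundary-segment rate.

    ``rate_px_per_frame`` is signed: positive means the edge moves toward
    larger position indices.  ``direction`` maps the sign onto the filament
    polarity when the caller declares which kymograph end is barbed
    (otherwise 'plus'/'minus' along the position axis).  ``weight`` is the
    position extent of the fitted span in pixels.
    """

    rate_px_per_frame: float
    rate_nm_per_s: Optional[float]
    direction: str  # toward_pointed | toward_barbed | plus | minus
    span: Tuple[Tuple[float, float], Tuple[float, float]]  # (pos, time) start/end
    weight: float
    side: str
    phase: str
    segment_id: int
    below_cutoff: Optional[bool] = None


@dataclass(frozen=True)
class CutoffFit:
    """Fitted minimum-measurable-rate cutoff (pixels/frame)."""

    r_cutoff: float
    residual: float
    n_pairs: int
    segment_length_range: Tuple[int, int] = (0, 0)


# ----------------------------------------------------------------- segment rates


def _fit_position_vs_time(verts: np.ndarray) -> float:
    """Slope (px/frame) of the LS line position = a + rate * time."""
    t = verts[:, 1]
    x = verts[:, 0]
    if len(verts) < 2:
        raise ValueError("need >= 2 vertices for a rate fit")
    vt = np.var(t)
    if vt == 0:
        raise ValueError("all vertices at the same time; rate undefined")
    return float(np.cov(t, x, bias=True)[0, 1] / vt)


def _direction_label(sign: float, polarity: Optional[str]) -> str:
    if polarity is None:
        return "plus" if sign >= 0 else "minus"
    if polarity not in ("p0-barbed", "p0-pointed"):
        raise ValueError(f"invalid polarity {polarity!r}")
    toward_p1 = sign >= 0
    if polarity == "p0-barbed":
        return "toward_pointed" if toward_p1 else "toward_barbed"
    return "toward_barbed" if toward_p1 else "toward_pointed"


def segment_rate(
    b: BoundarySet,
    p_start: Tuple[float, float],
    p_end: Tuple[float, float],
    polarity: Optional[str] = None,
    pixel_size_nm: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
) -> RateRecord:
    """Average rate between two points on one boundary segment.

    Fits position versus time over the boundary vertices lying between the
    two points (inclusive in position).
    """
    x0, x1 = sorted((p_start[0], p_end[0]))
    if x0 == x1:
        raise ValueError("rate between coincident positions is undefined")
    seg = _segment_containing(b, x0, x1)
    sel = (seg.vertices[:, 0] >= x0) & (seg.vertices[:, 0] <= x1)
    verts = seg.vertices[sel]
    rate_signed = _fit_position_vs_time(verts)  # sign: edge motion along + position axis
    nm_s = None
    if pixel_size_nm is not None and frame_interval_s is not None:
        nm_s = abs(rate_signed) * pixel_size_nm / frame_interval_s
    return RateRecord(
        rate_px_per_frame=rate_signed,
        rate_nm_per_s=nm_s,
        direction=_direction_label(rate_signed, polarity),
        span=(tuple(map(float, p_start)), tuple(map(float, p_end))),
        weight=float(x1 - x0),
        side=seg.side,
        phase=b.phase,
        segment_id=seg.seg_id,
    )


def _segment_containing(b: BoundarySet, x0: float, x1: float) -> Segment:
    for seg in b.segments:
        pos = seg.vertices[:, 0]
        if pos.min() <= x0 and pos.max() >= x1:
            return seg
    raise ValueError("no single segment spans both points")


def rates_from_events(
    b: BoundarySet,
    events: EventSet,
    polarity: Optional[str] = None,
    pixel_size_nm: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    r_cutoff: Optional[float] = None,
) -> List[RateRecord]:
    """Per-direction rate records from every nucleation (or DEP) outward.

    For each nucleation, two records span nucleation -> neighbouring stop
    point (the nearest meeting on the same segment or the segment end) in
    each growth direction.  Dissociation is handled analogously with DEPs as
    centres and DIPs as stop points.
    """
    if polarity is None:
        warnings.warn("no polarity declared; directions reported as plus/minus")
    if b.phase == "association":
        centres, stops = events.nucleations, events.meetings
    else:
        centres, stops = events.deps, events.dips
    if pixel_size_nm is None:
        pixel_size_nm = b.meta.get("pixel_size_nm")
    if frame_interval_s is None:
        frame_interval_s = b.meta.get("frame_interval_s")
    records: List[RateRecord] = []
    for ev in centres:
        try:
            seg = b.segment(ev.segment_id)
        except KeyError:
            continue
        pos = seg.vertices[:, 0]
        # stop points: segment ends plus meetings (DIPs) anywhere in the
        # segment's position range — a meeting of the first-bound side shows
        # on the inner boundary when the other side is already bound there
        stop_pos = sorted(
            {pos.min(), pos.max()}
            | {
                float(m.position)
                for m in stops
                if pos.min() <= m.position <= pos.max()
            }
        )
        left = max((p for p in stop_pos if p < ev.position), default=None)
        right = min((p for p in stop_pos if p > ev.position), default=None)
        for stop in (left, right):
            if stop is None or stop == ev.position:
                continue
            try:
                rec = segment_rate(
                    b,
                    (float(ev.position), ev.time),
                    (stop, float(_tau_at(seg, stop))),
                    polarity=polarity,
                    pixel_size_nm=pixel_size_nm,
                    frame_interval_s=frame_interval_s,
                )
            except ValueError:
                continue
            if r_cutoff is not None:
                rec = RateRecord(
                    **{**rec.__dict__, "below_cutoff": abs(rec.rate_px_per_frame) < r_cutoff}
                )
            records.append(rec)
    return records


def _tau_at(seg: Segment, x: float) -> float:
    idx = np.argmin(np.abs(seg.vertices[:, 0] - x))
    return float(seg.vertices[idx, 1])


# ----------------------------------------------------------------- aggregation


def weighted_average_rate(
    records: Sequence[RateRecord],
    direction: Optional[str] = None,
    weighting: str = "extent",
) -> float:
    """Weighted average of |rate| in nm/s (falls back to px/frame when no
    physical metadata is attached), weights = segment position extent."""
    recs = [r for r in records if direction is None or r.direction == direction]
    if not recs:
        raise ValueError(f"no rate records in direction {direction!r}")
    if weighting == "extent":
        w = np.array([r.weight for r in recs])
    elif weighting == "uniform":
        w = np.ones(len(recs))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    vals = np.array(
        [r.rate_nm_per_s if r.rate_nm_per_s is not None else abs(r.rate_px_per_frame)
         for r in recs]
    )
    return float(np.sum(w * vals) / np.sum(w))


def concentration_fit(
    points: Sequence[Tuple[float, float]],
    exclude_below: Optional[float] = None,
) -> float:
    """Through-origin least squares slope of rate vs feed concentration.

    slope = sum(c*r) / sum(c^2), in (rate units) per nM.  ``exclude_below``
    drops points whose concentration is below the given value (a feed
    concentration that may not reflect the true local concentration).
    """
    pts = [(c, r) for c, r in points if exclude_below is None or c >= exclude_below]
    if not pts:
        raise ValueError("no points to fit")
    c = np.array([p[0] for p in pts], dtype=float)
    r = np.array([p[1] for p in pts], dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    denom = float(np.sum(c * c))
    if denom == 0:
        raise ValueError("all concentrations zero")
    return float(np.sum(c * r) / denom)


# --------------------------------------------------------- simulated calibration


def edge_trace(mask: np.ndarray) -> np.ndarray:
    """Growing-tip position per frame: the largest on-position of a cleaned
    (position, frame) boundary mask; NaN for frames with no on-pixel."""
    n_pos, n_t = mask.shape
    out = np.full(n_t, np.nan)
    on = mask.any(axis=0)
    out[on] = n_pos - 1 - mask[::-1, on].argmax(axis=0)
    return out


def edge_trace_from_stack(stack: ImageStack, settings: ThresholdSettings) -> np.ndarray:
    """Tip-position trace of a simulated movie: kymograph along the filament
    row followed by boundary detection, as for experimental data.

    The first and last few frames are dropped (half the temporal median
    window plus the structuring-element size): the median filter and the
    erosion/dilation see past the ends of the recording there and deform the
    mask deterministically.
    """
    row = stack.meta.get("filament_row", stack.frame_shape[0] // 2)
    kym = extract_kymograph(stack, (row, 0), (row, stack.frame_shape[1] - 1), width=1)
    b = detect_boundaries(kym, settings, phase="association")
    if 1 not in b.masks or not b.masks[1].any():
        raise ValueError("no boundary detected in simulated stack")
    trim = settings.median_window[1] // 2 + settings.structuring_element[1] + 1
    e = edge_trace(b.masks[1])
    return e[trim : len(e) - trim] if len(e) > 2 * trim + 2 else e


def rate_from_edge(e: np.ndarray, segment_length: int, estimator: str = "mean") -> float:
    """|LS slope| of a tip trace over sliding windows spanning
    ``segment_length`` frame intervals, aggregated over windows.

    Windows slide by one frame (a continuous measure along the boundary):
    each boundary step is then seen at every within-window phase, which
    keeps the estimator unbiased when steps are periodic in time.
    """
    k = int(segment_length)
    if k < 1:
        raise ValueError("segment_length must be >= 1")
    e = np.asarray(e, dtype=float)
    if len(e) < k + 1:
        raise ValueError(f"boundary too short for segment_length={k}")
    # vectorised LS slope over all length-(k+1) sliding windows
    t = np.arange(k + 1) - k / 2.0
    denom = float(np.sum(t**2))
    kernel = t / denom
    valid = np.isfinite(e)
    if k == 1:
        slopes = np.abs(np.diff(e))
        slopes = slopes[np.isfinite(slopes)]
    else:
        conv = np.correlate(np.where(valid, e, 0.0), kernel, mode="valid")
        window_ok = (
            np.correlate((~valid).astype(float), np.ones(k + 1), mode="valid") == 0
        )
        slopes = np.abs(conv[window_ok])
    if slopes.size == 0:
        raise ValueError(f"boundary too short for segment_length={k}")
    if estimator == "mean":
        return float(np.mean(slopes))
    if estimator == "median":
        return float(np.median(slopes))
    raise ValueError(f"unknown estimator {estimator!r}")


def measure_rate_from_stack(
    stack: ImageStack,
    settings: ThresholdSettings,
    segment_length: int,
    estimator: str = "mean",
) -> float:
    """Measured elongation rate M of one simulated movie (pixels/frame),
    via the experimental kymograph -> boundary -> segment-fit pipeline."""
    return rate_from_edge(edge_trace_from_stack(stack, settings), segment_length, estimator)


def measure_simulated_rates(
    stacks: Iterable[Tuple[ImageStack, float]],
    settings: ThresholdSettings,
    segment_length: int,
    estimator: str = "mean",
) -> List[Tuple[float, float]]:
    """Paired (actual, measured) rates for a set of simulated movies.

    Stacks whose boundary is too short for the requested segment length are
    skipped with a warning.
    """
    pairs: List[Tuple[float, float]] = []
    for stack, true_rate in stacks:
        try:
            m = measure_rate_from_stack(stack, settings, segment_length, estimator)
        except ValueError as err:
            warnings.warn(f"skipping stack (A={true_rate}): {err}")
            continue
        pairs.append((float(true_rate), m))
    return pairs


def fit_cutoff(pairs: Sequence[Tuple[float, float]]) -> CutoffFit:
    """Least-squares fit of the piecewise cutoff model to (A, M) pairs.

    M = R for A < R and M = A for A >= R.  Within a fixed membership split
    the optimal R is the mean of the below-cutoff M values, so the global
    optimum is found exactly by enumerating splits of the A-sorted pairs.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 (A, M) pairs")
    arr = np.array(sorted(pairs), dtype=float)
    A, M = arr[:, 0], arr[:, 1]
    n = len(A)
    csum = np.concatenate([[0.0], np.cumsum(M)])
    csum2 = np.concatenate([[0.0], np.cumsum(M**2)])
    tail_sse = np.concatenate([np.cumsum(((M - A) ** 2)[::-1])[::-1], [0.0]])
    best = None
    for s in range(1, n):  # pairs [0, s) below cutoff, [s, n) above
        r = csum[s] / s
        below_sse = csum2[s] - s * r**2
        rss = below_sse + tail_sse[s]
        consistent = (A[s - 1] < r) and (r <= A[s])
        cand = (not consistent, rss, r)  # prefer consistent, then lowest RSS
        if best is None or cand < best:
            best = cand
    inconsistent, rss, r = best
    if r <= A[0] or r > A[-1]:
        raise ValueError("cutoff unidentifiable: all pairs on one side")
    return CutoffFit(r_cutoff=float(r), residual=float(max(rss, 0.0)), n_pairs=n)
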