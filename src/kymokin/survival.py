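"""Nucleation kinetics via Kaplan-Meier survival analysis.

Nucleation on a filament is a point process on the available sites: pixels
neither occupied by bound protein nor adjacent to an occupied pixel (the
neighbours are elongation sites, not nucleation sites).  With d_i the number
of nucleation events occurring at frame i and n_i the number of available
sites at frame i, the survival estimator

    S(t) = prod_{i < t} (1 - d_i / n_i)

is the probability that a given available site has not yet nucleated by
time t.  The characteristic nucleation time t_nuc is obtained from a
least-squares fit of exp(-t / t_nuc) to the estimator steps; estimators
from filaments recorded under the same conditions can be pooled (summing
d_i and n_i per frame) before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy import ndimage, optimize


@dataclass
class SurvivalCurve:
    """Kaplan-Meier estimator with its per-step event and at-risk counts.

    ``times``/``S``/``d``/``n`` are per-step arrays (steps at frames with
    at least one event); ``n_series`` keeps the full at-risk count per frame
    so curves can be pooled.  ``censored`` is True when the recording ended
    before the risk set emptied.
    """

    times: np.ndarray  # frames of the steps
    S: np.ndarray  # estimator value just after each step
    d: np.ndarray  # events at each step
    n: np.ndarray  # at-risk sites at each step
    censored: bool
    end_frame: int
    n_series: np.ndarray  # at-risk sites for every frame [0, end_frame)
    frame_interval_s: float = 1.0

    def validate(self) -> None:
        if np.any(self.d > self.n):
            raise AssertionError("d_i <= n_i violated")
        if self.S.size:
            if self.S[0] > 1.0 + 1e-12 or np.any(self.S < -1e-12):
                raise AssertionError("S out of [0, 1]")
            if np.any(np.diff(self.S) > 1e-12):
                raise AssertionError("S must be non-increasing")


def available_sites(occupancy: np.ndarray) -> np.ndarray:
    """At-risk nucleation sites per frame from a (pixel, frame) occupancy mask.

    n_i = L - |occupied U neighbours-of-occupied| at frame i.
    """
    occ = np.asarray(occupancy, dtype=bool)
    if occ.ndim != 2:
        raise ValueError("occupancy must be 2-D (pixel, frame)")
    excluded = ndimage.binary_dilation(
        occ, structure=np.array([[1], [1], [1]], dtype=bool)
    )
    return occ.shape[0] - excluded.sum(axis=0)


def km_estimator(
    event_frames: Sequence[int],
    n_series: np.ndarray,
    end_frame: int,
    frame_interval_s: float = 1.0,
) -> SurvivalCurve:
    """Kaplan-Meier estimator from nucleation frames and the at-risk series.

    d_i counts the events occurring AT frame i; the estimator steps down by
    the factor (1 - d_i/n_i) at each event frame and is right-censored at
    ``end_frame`` if the recording ends without emptying the risk set.
    """
    n_series = np.asarray(n_series)
    if len(n_series) < end_frame:
        raise ValueError("n_series shorter than end_frame")
    frames = np.asarray(sorted(event_frames), dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= end_frame):
        raise ValueError("every event frame must lie in [0, end_frame)")
    step_frames, counts = np.unique(frames, return_counts=True)
    n_at = n_series[step_frames] if step_frames.size else np.array([], dtype=int)
    if np.any(counts > n_at):
        raise ValueError("more events than available sites at a frame")
    factors = 1.0 - counts / n_at.astype(float) if step_frames.size else np.array([])
    S = np.cumprod(factors)
    censored = bool(S.size == 0 or S[-1] > 0.0)
    curve = SurvivalCurve(
        times=step_frames.astype(float),
        S=S,
        d=counts,
        n=n_at,
        censored=censored,
        end_frame=int(end_frame),
        n_series=n_series[:end_frame].copy(),
        frame_interval_s=frame_interval_s,
    )
    curve.validate()
    return curve


def pool_estimators(curves: Sequence[SurvivalCurve]) -> SurvivalCurve:
    """Combine estimators from filaments recorded under the same conditions.

    Event counts and at-risk counts are summed per frame across curves and
    the product recomputed.  All curves must share the frame interval.
    """
    if not curves:
        raise ValueError("no curves to pool")
    dt = curves[0].frame_interval_s
    if any(c.frame_interval_s != dt for c in curves):
        raise ValueError("mismatched frame intervals")
    end = max(c.end_frame for c in curves)
    n_total = np.zeros(end, dtype=float)
    d_total = np.zeros(end, dtype=float)
    for c in curves:
        n_total[: c.end_frame] += c.n_series
        for t, d in zip(c.times.astype(int), c.d):
            d_total[t] += d
    event_frames = []
    for t in np.nonzero(d_total)[0]:
        event_frames.extend([int(t)] * int(d_total[t]))
    return km_estimator(event_frames, n_total, end, frame_interval_s=dt)


def occupancy_from_boundaries(tau_outer: np.ndarray, frame_range) -> np.ndarray:
    """Bound-region occupancy mask (pixel, frame) implied by an association
    boundary: pixel x is occupied from its first-bound frame tau_outer(x) on.

    This is the merged (either-side) mask — the conservative at-risk
    accounting when side labels are unavailable.
    """
    start, stop = frame_range
    frames = np.arange(start, stop)[None, :]
    tau = np.asarray(tau_outer, dtype=float)[:, None]
    return np.where(np.isfinite(tau), frames >= tau, False)


class UnidentifiableNucleationTime(ValueError):
    """Raised when no events were observed; carries the identifiable lower bound."""

    def __init__(self, lower_bound_s: float):
        super().__init__(
            f"t_nuc unidentifiable: no events observed; t_nuc > ~{lower_bound_s:.3g} s"
        )
        self.lower_bound_s = lower_bound_s


@dataclass(frozen=True)
class NucleationFit:
    """Characteristic nucleation time from an exponential-decay fit to S(t)."""

    t_nuc_s: float
    fit_rss: float
    n_events: int
    censored: bool


def fit_nucleation_time(
    curve: SurvivalCurve, frame_interval_s: Optional[float] = None
) -> NucleationFit:
    """Least-squares fit of exp(-t/t_nuc) to the estimator steps.

    The fit uses the S values at the step times (left-edge convention),
    with t in seconds.  Deterministic 1-D optimisation.
    """
    if frame_interval_s is None:
        frame_interval_s = curve.frame_interval_s
    if curve.S.size == 0:
        raise UnidentifiableNucleationTime(curve.end_frame * frame_interval_s)
    t = curve.times * frame_interval_s
    s = curve.S

    def rss(log_tau: float) -> float:
        return float(np.sum((s - np.exp(-t / np.exp(log_tau))) ** 2))

    # bracket from a crude regression of log S on t, then refine
    pos = s > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope = np.polyfit(t[pos], np.log(s[pos]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else float(t.max() or 1.0)
    else:
        tau0 = float(max(t.max(), frame_interval_s))
    tau0 = float(np.clip(tau0, 1e-6, 1e12))
    res = optimize.minimize_scalar(
        rss,
        bounds=(np.log(tau0) - 6.0, np.log(tau0) + 6.0),
        method="bounded",
        options={"xatol": 1e-12},
    )
    t_nuc = float(np.exp(res.x))
    return NucleationFit(
        t_nuc_s=t_nuc,
        fit_rss=float(res.fun),
        n_events=int(curve.d.sum()),
        censored=curve.censored,
    )
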