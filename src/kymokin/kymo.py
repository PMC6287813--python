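"""Kymograph construction from image stacks along straight filament paths.

A kymograph collapses a movie to a 2-D array: intensity along a 1-D path
(the filament backbone) versus time.  Position is the first axis so the
filament runs vertically when displayed, time horizontally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .stack import ImageStack


@dataclass
class Kymograph:
    """2-D intensity array indexed [position_pixel][frame] plus acquisition metadata."""

    intensity: np.ndarray
    pixel_size_nm: float
    frame_interval_assoc_s: float
    frame_interval_dissoc_s: Optional[float] = None
    phase_boundary_index: Optional[int] = None
    source_path: Optional[tuple] = None  # ((row0,col0),(row1,col1))
    averaging_width: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("kymograph intensity must be 2-D (position, frame)")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("kymograph intensity must be finite")
        pb = self.phase_boundary_index
        if pb is not None and not (1 <= pb <= self.n_frames - 1):
            raise ValueError("phase_boundary_index out of range")

    @property
    def n_positions(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]

    def frame_time(self, k: int) -> float:
        pb = self.phase_boundary_index
        if pb is None or k < pb:
            return k * self.frame_interval_assoc_s
        dt = self.frame_interval_dissoc_s or self.frame_interval_assoc_s
        return pb * self.frame_interval_assoc_s + (k - pb) * dt

    def phase_frames(self, phase: str) -> tuple[int, int]:
        """Frame range [start, stop) of a phase ('association' or 'dissociation')."""
        pb = self.phase_boundary_index
        if phase == "association":
            return (0, self.n_frames if pb is None else pb)
        if phase == "dissociation":
            if pb is None:
                return (0, self.n_frames)
            return (pb, self.n_frames)
        raise ValueError(f"unknown phase {phase!r}")


@dataclass
class RoiTrace:
    """Total intensity of a rectangular ROI per frame."""

    time_s: np.ndarray
    total_intensity: np.ndarray
    roi: tuple  # (row0, row1, col0, col1), half-open

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.total_intensity):
            raise ValueError("time and intensity lengths differ")


def _path_samples(p0, p1, width: int):
    """Sample coordinates along p0->p1 at unit steps, with symmetric
    perpendicular offsets for width averaging.

    Returns (rows, cols) arrays of shape (n_samples, width).
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    length = float(np.hypot(*d))
    if length < 2.0:
        raise ValueError("path shorter than 2 pixels")
    n = int(round(length)) + 1
    u = d / length
    perp = np.array([-u[1], u[0]])
    ts = np.linspace(0.0, length, n)
    offsets = np.arange(width) - (width - 1) / 2.0
    pts = p0[None, None, :] + ts[:, None, None] * u[None, None, :] \
        + offsets[None, :, None] * perp[None, None, :]
    return pts[..., 0], pts[..., 1]


def extract_kymograph(
    stack: ImageStack,
    p0: Sequence[float],
    p1: Sequence[float],
    width: int = 1,
) -> Kymograph:
    """Build a kymograph by averaging intensity along a straight path.

    For each frame the image is sampled at unit-pixel steps along the segment
    ``p0 -> p1`` (bilinear interpolation) and averaged over ``width`` samples
    taken perpendicular to the path.  Position 0 of the kymograph is ``p0``.
    """
    if width < 1 or width % 2 == 0:
        raise ValueError("width must be an odd integer >= 1")
    rows, cols = _path_samples(p0, p1, width)
    nr, nc = stack.frame_shape
    if rows.min() < -1e-9 or cols.min() < -1e-9 or rows.max() > nr - 1 + 1e-9 \
            or cols.max() > nc - 1 + 1e-9:
        raise ValueError("path (after width broadening) leaves the image")
    coords = np.stack([rows.ravel(), cols.ravel()])
    out = np.empty((rows.shape[0], stack.n_frames))
    for k in range(stack.n_frames):
        samp = ndimage.map_coordinates(
            np.asarray(stack.data[k], dtype=float), coords, order=1, mode="nearest"
        ).reshape(rows.shape)
        out[:, k] = samp.mean(axis=1)
    return Kymograph(
        intensity=out,
        pixel_size_nm=stack.pixel_size_nm,
        frame_interval_assoc_s=stack.frame_interval_s,
        frame_interval_dissoc_s=stack.frame_interval_dissoc_s,
        phase_boundary_index=stack.phase_boundary_index,
        source_path=(tuple(np.asarray(p0, float)), tuple(np.asarray(p1, float))),
        averaging_width=width,
    )


def roi_total_intensity(stack: ImageStack, roi: Sequence[int]) -> RoiTrace:
    """Per-frame summed intensity over a rectangular ROI (row0,row1,col0,col1), half-open."""
    r0, r1, c0, c1 = (int(v) for v in roi)
    nr, nc = stack.frame_shape
    if not (0 <= r0 < r1 <= nr and 0 <= c0 < c1 <= nc):
        raise ValueError("ROI empty or out of bounds")
    total = np.asarray(stack.data, dtype=float)[:, r0:r1, c0:c1].sum(axis=(1, 2))
    times = np.array([stack.frame_time(k) for k in range(stack.n_frames)])
    return RoiTrace(time_s=times, total_intensity=total, roi=(r0, r1, c0, c1))
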