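"""Image-stack container shared by the simulation, registration and kymograph modules."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


@dataclass
class ImageStack:
    """A TIRF time-lapse: 3-D intensity array indexed (frame, row, col).

    The stack may hold a single acquisition phase or the concatenation of an
    association phase and a dissociation phase recorded at different frame
    rates; ``phase_boundary_index`` is the frame index of the first
    dissociation frame (``None`` for a single-phase stack).

    Physical metadata is carried explicitly: ``pixel_size_nm`` (nm per pixel)
    and the per-phase frame intervals in seconds.
    """

    data: np.ndarray
    pixel_size_nm: float
    frame_interval_s: float
    frame_interval_dissoc_s: Optional[float] = None
    phase_boundary_index: Optional[int] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be 3-D (frame,row,col); got {self.data.ndim}-D")
        if self.pixel_size_nm <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_nm and frame_interval_s must be positive")
        if self.phase_boundary_index is not None and not (
            1 <= self.phase_boundary_index <= self.n_frames - 1
        ):
            raise ValueError("phase_boundary_index out of range")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def frame_time(self, k: int) -> float:
        """Timestamp (s) of frame ``k`` using the per-phase frame intervals.

        Each phase's clock starts at its first frame; the dissociation phase
        continues from the end of the association phase.
        """
        pb = self.phase_boundary_index
        if pb is None or k < pb:
            return k * self.frame_interval_s
        dt = self.frame_interval_dissoc_s
        if dt is None:
            dt = self.frame_interval_s
        return pb * self.frame_interval_s + (k - pb) * dt

    def copy_with(self, **kw) -> "ImageStack":
        return replace(self, **kw)
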