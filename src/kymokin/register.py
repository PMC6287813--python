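"""Rigid alignment of association and dissociation image stacks.

The two phases are acquired as separate movies (typically at different frame
rates), so before a joint kymograph can be extracted the dissociation stack
must be mapped into the association frame of reference.  Images are assumed
undistorted: a rigid transform (rotation about the image centre plus
translation) is optimised against the mean-squared intensity difference of
one frame pair (by default the last association frame and the first
dissociation frame) using regular-step gradient descent — the step is halved
whenever the descent direction reverses, and iteration stops when the step
falls below ``min_step``.  Only improving steps are accepted, so the
sequence of accepted metric values is non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .stack import ImageStack


@dataclass(frozen=True)
class RigidTransform:
    """Rotation (degrees, about ``center``) followed by translation (pixels).

    Maps coordinates x = (row, col) to R(theta) @ (x - c) + c + t.
    """

    rotation_deg: float = 0.0
    translation_row: float = 0.0
    translation_col: float = 0.0
    center: Tuple[float, float] = (0.0, 0.0)

    def matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center)
        t = np.array([self.translation_row, self.translation_col])
        return (self.matrix() @ (pts - c).T).T + c + t

    def inverse(self) -> "RigidTransform":
        rinv = self.matrix().T
        t = np.array([self.translation_row, self.translation_col])
        # x = R^-1 (y - c - t) + c  =  R^-1 (y - c) + c + [R^-1 (-t)]... solve properly:
        # y = R (x - c) + c + t  =>  x = R^T (y - c - t) + c
        #   = R^T (y - c) + c + (R^T (-t))
        t_inv = -(rinv @ t)
        return RigidTransform(
            rotation_deg=-self.rotation_deg,
            translation_row=float(t_inv[0]),
            translation_col=float(t_inv[1]),
            center=self.center,
        )

    @property
    def is_identity(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.translation_row == 0.0
            and self.translation_col == 0.0
        )


@dataclass(frozen=True)
class RegistrationSettings:
    metric: str = "mean_squared_difference"
    optimizer: str = "regular_step_gradient_descent"
    initial_step: float = 2.0
    min_step: float = 1e-4
    max_iterations: int = 300
    pyramid_levels: int = 3
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.metric != "mean_squared_difference":
            raise ValueError("only the mean_squared_difference metric is supported")
        if self.optimizer != "regular_step_gradient_descent":
            raise ValueError("only regular_step_gradient_descent is supported")
        if not self.min_step < self.initial_step:
            raise ValueError("min_step must be < initial_step")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")


def _resample(image: np.ndarray, t: RigidTransform, fill: float) -> np.ndarray:
    """Apply a rigid transform to an image (bilinear, pull-back resampling)."""
    if t.is_identity:
        return image.copy()
    inv = t.inverse()
    c = np.asarray(inv.center)
    offset = -inv.matrix() @ c + c + np.array([inv.translation_row, inv.translation_col])
    return ndimage.affine_transform(
        np.asarray(image, dtype=float),
        inv.matrix(),
        offset=offset,
        order=1,
        mode="constant",
        cval=fill,
    )


def _metric(fixed: np.ndarray, moving: np.ndarray, t: RigidTransform, fill: float) -> float:
    resampled = _resample(moving, t, fill)
    return float(np.mean((fixed - resampled) ** 2))


def _downsample(img: np.ndarray) -> np.ndarray:
    sm = ndimage.gaussian_filter(np.asarray(img, dtype=float), 1.0)
    return sm[::2, ::2]


def register_rigid(
    fixed: np.ndarray,
    moving: np.ndarray,
    settings: RegistrationSettings = RegistrationSettings(),
    trace: Optional[List[float]] = None,
) -> Tuple[RigidTransform, float]:
    """Estimate the rigid transform T minimising MSE(fixed, T(moving)).

    Regular-step gradient descent on (rotation, translation): a step along
    the negative normalised gradient is taken when it improves the metric;
    the step length is halved on gradient-direction reversal or on a failed
    step; iteration ends when the step falls below ``min_step``.  A
    coarse-to-fine pyramid (``pyramid_levels``) improves the capture range.
    Deterministic for fixed inputs and settings.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if fixed.shape != moving.shape:
        raise ValueError("fixed and moving images must have the same shape")
    if not (np.all(np.isfinite(fixed)) and np.all(np.isfinite(moving))):
        raise ValueError("images must be finite")
    # pyramid: level 0 = full resolution
    pyr_f, pyr_m = [fixed], [moving]
    for _ in range(settings.pyramid_levels - 1):
        if min(pyr_f[-1].shape) < 16:
            break
        pyr_f.append(_downsample(pyr_f[-1]))
        pyr_m.append(_downsample(pyr_m[-1]))
    theta, tr, tc = 0.0, 0.0, 0.0
    for level in reversed(range(len(pyr_f))):
        scale = 2**level
        f, m = pyr_f[level], pyr_m[level]
        center = ((f.shape[0] - 1) / 2.0, (f.shape[1] - 1) / 2.0)
        p = np.array([theta, tr / scale, tc / scale])
        p = _rsgd(f, m, p, center, settings, trace if level == 0 else None)
        theta, tr, tc = p[0], p[1] * scale, p[2] * scale
    center_full = ((fixed.shape[0] - 1) / 2.0, (fixed.shape[1] - 1) / 2.0)
    best = RigidTransform(theta, tr, tc, center_full)
    final = _metric(fixed, moving, best, settings.fill_value)
    m0 = _metric(fixed, moving, RigidTransform(center=center_full), settings.fill_value)
    if final >= m0 and m0 > 0:
        warnings.warn("registration failed to improve the metric; returning identity")
        return RigidTransform(center=center_full), m0
    return best, final


def _rsgd(
    fixed: np.ndarray,
    moving: np.ndarray,
    p0: np.ndarray,
    center: Tuple[float, float],
    s: RegistrationSettings,
    trace: Optional[List[float]] = None,
) -> np.ndarray:
    """Regular-step gradient descent at one pyramid level.

    ``trace``, if given, collects the accepted metric values (non-increasing
    by construction: a trial step is only accepted when it improves).
    """

    def metric(p: np.ndarray) -> float:
        return _metric(
            fixed, moving, RigidTransform(p[0], p[1], p[2], center), s.fill_value
        )

    p = p0.copy()
    m = metric(p)
    if trace is not None:
        trace.append(m)
    step = s.initial_step
    prev_dir: Optional[np.ndarray] = None
    h = 0.25
    for _ in range(s.max_iterations):
        g = np.array(
            [
                (metric(p + dh) - metric(p - dh)) / (2 * h)
                for dh in (np.array([h, 0, 0]), np.array([0, h, 0]), np.array([0, 0, h]))
            ]
        )
        norm = np.linalg.norm(g)
        if norm == 0:
            break
        d = -g / norm
        if prev_dir is not None and float(d @ prev_dir) < 0:
            step *= 0.5
        if step < s.min_step:
            break
        trial = p + step * d
        m_trial = metric(trial)
        if m_trial < m:
            p, m = trial, m_trial
            prev_dir = d
            if trace is not None:
                trace.append(m)
        else:
            step *= 0.5
        h = max(min(h, step), 1e-4)
    return p


def apply_transform(stack: ImageStack, t: RigidTransform, fill: float = 0.0) -> ImageStack:
    """Resample every frame of a stack with the same rigid transform."""
    if t.is_identity:
        return stack.copy_with(data=stack.data.copy())
    out = np.stack([_resample(frame, t, fill) for frame in stack.data])
    return stack.copy_with(data=out)


def concatenate_phases(
    assoc: ImageStack, dissoc: ImageStack, t: RigidTransform, fill: float = 0.0
) -> ImageStack:
    """Map the dissociation stack into the association frame and append it.

    The returned stack carries ``phase_boundary_index = assoc.n_frames`` and
    both per-phase frame intervals.
    """
    if assoc.frame_shape != dissoc.frame_shape:
        raise ValueError("association and dissociation frames differ in shape")
    moved = apply_transform(dissoc, t, fill)
    data = np.concatenate([np.asarray(assoc.data, float), np.asarray(moved.data, float)])
    return ImageStack(
        data=data,
        pixel_size_nm=assoc.pixel_size_nm,
        frame_interval_s=assoc.frame_interval_s,
        frame_interval_dissoc_s=dissoc.frame_interval_s,
        phase_boundary_index=assoc.n_frames,
        meta={**assoc.meta, "registration": t},
    )
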