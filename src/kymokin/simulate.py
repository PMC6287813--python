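"""Synthetic TIRF data generators.

Two generators are provided:

* :func:`simulate_growing_filament_stack` renders movies of a 1-pixel-wide
  straight filament elongating at a known rate, blurred by a Gaussian PSF and
  corrupted by camera noise.  These movies are the input for calibrating the
  pixelation/resolution-limited rate cutoff (``rates.fit_cutoff``).

* :func:`simulate_two_sided_kymograph` generates three-level kymographs by
  stochastic nucleation and bidirectional strand elongation on the two
  independent sides (grooves) of a 1-D lattice, with full ground truth
  (occupancy, boundary curves, nucleation / meeting / dissociation events).
  This emulates a protein such as tropomyosin that polymerises head-to-tail
  along each of the two grooves of an actin filament, so that a kymograph
  pixel shows background, single-bound or double-bound intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage

from .kymo import Kymograph
from .stack import ImageStack

# --------------------------------------------------------------------------- noise


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise model.

    ``gaussian`` adds i.i.d. zero-mean read noise of sd ``read_sigma``.
    ``poisson_gaussian`` draws a Poisson variate on ``gain``-scaled
    intensities (shot noise) and then adds Gaussian read noise — the usual
    EMCCD phenomenology.  ``none`` is exact pass-through.
    """

    kind: str = "none"  # none | gaussian | poisson_gaussian
    read_sigma: float = 0.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson_gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")


def add_noise(image: np.ndarray, model: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Apply a noise model to an image; deterministic given the generator state."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    if model.kind == "none":
        return image
    if model.kind == "gaussian":
        return image + rng.normal(0.0, model.read_sigma, size=image.shape)
    # poisson_gaussian
    if np.any(image < 0):
        raise ValueError("poisson_gaussian noise requires non-negative intensities")
    shot = rng.poisson(image * model.gain) / model.gain
    return shot + rng.normal(0.0, model.read_sigma, size=image.shape)


# ------------------------------------------------------------------- growing movie


@dataclass(frozen=True)
class GrowthSimConfig:
    """Configuration for a movie of a single filament elongating at a fixed rate.

    The filament is a 1-pixel-wide horizontal segment; one end (the tethered
    end) is stationary and the other extends at ``growth_rate`` pixels/frame.
    Length is accumulated as a real number and rendered by rounding to whole
    pixels, reproducing the pixelation that limits slow-rate measurements.
    """

    image_height: int = 16
    image_width: int = 96
    initial_length: float = 20.0
    growth_rate: float = 0.01  # pixels / frame
    n_frames: int = 200
    psf_sigma: float = 2.5  # pixels
    filament_intensity: float = 100.0
    background_level: float = 10.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    pixel_size_nm: float = 100.0
    frame_interval_s: float = 10.0  # 0.1 Hz
    start_col: int = 4
    grow_from_start: bool = False  # tethered end is start_col; growth extends to larger cols

    def __post_init__(self) -> None:
        if self.growth_rate < 0:
            raise ValueError("growth_rate must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.initial_length < 1:
            raise ValueError("initial_length must be >= 1")


def _render_length(length: float) -> int:
    # round-half-up to avoid numpy's banker's rounding
    return int(math.floor(length + 0.5))


def simulate_growing_filament_stack(config: GrowthSimConfig) -> ImageStack:
    """Render the movie described by ``config``.

    In frame ``k`` the pre-convolution filament occupies
    ``round(initial_length + growth_rate * k)`` pixels from the tethered end;
    each frame is convolved with a 2-D Gaussian of sd ``psf_sigma`` and noise
    is applied per the configured model.
    """
    c = config
    rng = np.random.default_rng(c.seed)
    row = c.image_height // 2
    frames = np.empty((c.n_frames, c.image_height, c.image_width))
    for k in range(c.n_frames):
        length = _render_length(c.initial_length + c.growth_rate * k)
        if c.start_col + length > c.image_width:
            raise ValueError(
                f"filament exceeds frame bounds at frame {k} "
                f"(length {length} px from column {c.start_col})"
            )
        img = np.zeros((c.image_height, c.image_width))
        img[row, c.start_col : c.start_col + length] = c.filament_intensity
        img = ndimage.gaussian_filter(img, c.psf_sigma)
        img += c.background_level
        frames[k] = add_noise(img, c.noise, rng)
    return ImageStack(
        data=frames,
        pixel_size_nm=c.pixel_size_nm,
        frame_interval_s=c.frame_interval_s,
        meta={"seed": c.seed, "growth_rate": c.growth_rate, "filament_row": row,
              "start_col": c.start_col},
    )


# --------------------------------------------------------------- two-sided lattice


@dataclass(frozen=True)
class LatticeSimConfig:
    """Two-sided 1-D lattice simulation of nucleation / elongation / dissociation.

    During the association phase, nucleations occur on each side independently
    as a Bernoulli process per available site per frame; an available site is a
    pixel neither occupied on that side nor adjacent to an occupied pixel on
    that side (neighbouring pixels are elongation, not nucleation, sites).
    Each nucleus elongates at ``elongation_rate`` pixels/frame in both
    directions until it meets another strand on the same side or a filament
    end.  During the dissociation phase no new nucleation occurs and each
    strand end retracts stochastically at ``dissociation_end_rate`` per
    strand-end per frame.
    """

    lattice_length: int = 100
    n_frames_assoc: int = 200
    n_frames_dissoc: int = 0
    nucleation_rate: float = 0.0  # events / (site * frame)
    elongation_rate: float = 0.5  # pixels / frame (per direction)
    dissociation_end_rate: float = 0.0  # events / (strand-end * frame)
    level_step: float = 10.0  # intensity added per bound side
    background_level: float = 5.0
    noise_sigma: float = 0.0
    psf_sigma_kymo: float = 0.0  # blur along the position axis; 0 = none
    seed: int = 0
    pixel_size_nm: float = 92.0
    frame_interval_assoc_s: float = 1.0
    frame_interval_dissoc_s: float = 1.0
    forced_nucleations: Tuple[Tuple[int, int, int], ...] = ()  # (side, pixel, frame)

    def __post_init__(self) -> None:
        if self.lattice_length < 3:
            raise ValueError("lattice_length must be >= 3")
        if self.n_frames_assoc < 1:
            raise ValueError("n_frames_assoc must be >= 1")
        if min(self.nucleation_rate, self.elongation_rate,
               self.dissociation_end_rate, self.noise_sigma) < 0:
            raise ValueError("rates and noise_sigma must be >= 0")
        for side, pixel, frame in self.forced_nucleations:
            if side not in (0, 1) or not (0 <= pixel < self.lattice_length) \
                    or not (0 <= frame < self.n_frames_assoc):
                raise ValueError(f"invalid forced nucleation {(side, pixel, frame)}")


@dataclass
class GroundTruth:
    """Everything the simulator knows: occupancy, events and boundary curves.

    Boundary curves use the first-bound-frame convention for association
    (``tau1_assoc`` = first frame any side occupies pixel x, ``tau2_assoc`` =
    first frame both sides do) and the last-bound-frame convention for
    dissociation.  Undefined values are NaN.  Frames are absolute indices into
    the concatenated (association + dissociation) timeline.
    """

    occupancy: np.ndarray  # (2, lattice_length, n_frames_total) bool
    nucleations: List[Tuple[int, int, int]]  # (side, pixel, frame)
    meetings: List[Tuple[int, int, int]]
    dips: List[Tuple[int, int, int]]
    deps: List[Tuple[int, int, int]]
    tau1_assoc: np.ndarray
    tau2_assoc: np.ndarray
    tau1_dissoc: np.ndarray
    tau2_dissoc: np.ndarray
    seed: int
    config: LatticeSimConfig


class _Strand:
    __slots__ = ("lo_f", "hi_f", "frozen_lo", "frozen_hi", "born")

    def __init__(self, pixel: int, frame: int):
        self.lo_f = float(pixel)
        self.hi_f = float(pixel)
        self.frozen_lo = False
        self.frozen_hi = False
        self.born = frame

    @property
    def lo(self) -> int:
        return _render_length(self.lo_f) - 0  # round-half-up

    @property
    def hi(self) -> int:
        return _render_length(self.hi_f)


def _occupied_mask(strands: List[_Strand], length: int) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for s in strands:
        mask[max(s.lo, 0) : min(s.hi, length - 1) + 1] = True
    return mask


def _available_sites_mask(occ: np.ndarray) -> np.ndarray:
    """Pixels not occupied and not adjacent to an occupied pixel."""
    excluded = ndimage.binary_dilation(occ, structure=np.ones(3, dtype=bool))
    return ~excluded


def simulate_two_sided_kymograph(
    config: LatticeSimConfig,
) -> Tuple[Kymograph, GroundTruth]:
    """Run the lattice simulation and build the (optionally blurred/noisy) kymograph."""
    c = config
    rng = np.random.default_rng(c.seed)
    L, Ta, Td = c.lattice_length, c.n_frames_assoc, c.n_frames_dissoc
    T = Ta + Td
    occ = np.zeros((2, L, T), dtype=bool)
    strands: List[List[_Strand]] = [[], []]
    nucleations: List[Tuple[int, int, int]] = []
    meetings: List[Tuple[int, int, int]] = []
    dips: List[Tuple[int, int, int]] = []
    deps: List[Tuple[int, int, int]] = []
    forced_by_frame: dict = {}
    for side, pixel, frame in c.forced_nucleations:
        forced_by_frame.setdefault(frame, []).append((side, pixel))

    # ---------------- association phase
    for t in range(Ta):
        for side in (0, 1):
            ss = strands[side]
            # elongate strands nucleated at earlier frames
            for s in ss:
                if s.born < t:
                    if not s.frozen_lo:
                        s.lo_f = max(s.lo_f - c.elongation_rate, 0.0)
                    if not s.frozen_hi:
                        s.hi_f = min(s.hi_f + c.elongation_rate, L - 1.0)
            # resolve meetings between neighbouring strands on this side
            ss.sort(key=lambda s: s.lo_f)
            for a, b in zip(ss, ss[1:]):
                if not a.frozen_hi or not b.frozen_lo:
                    if a.hi + 1 >= b.lo:
                        m = (a.hi + b.lo) // 2
                        m = max(a.lo, min(m, b.hi - 1))
                        a.hi_f = float(m)
                        b.lo_f = float(m + 1)
                        a.frozen_hi = True
                        b.frozen_lo = True
                        meetings.append((side, m, t))
            # nucleation: forced first, then stochastic on available sites
            occ_now = _occupied_mask(ss, L)
            avail = _available_sites_mask(occ_now)
            for fs, fp in forced_by_frame.get(t, []):
                if fs == side:
                    ss.append(_Strand(fp, t))
                    nucleations.append((side, fp, t))
                    occ_now[fp] = True
                    avail = _available_sites_mask(occ_now)
            if c.nucleation_rate > 0:
                draws = rng.random(L) < c.nucleation_rate
                for x in np.nonzero(draws & avail)[0]:
                    if avail[x]:  # re-check: an earlier draw may have claimed a neighbour
                        ss.append(_Strand(int(x), t))
                        nucleations.append((side, int(x), t))
                        occ_now[x] = True
                        avail = _available_sites_mask(occ_now)
            occ[side, :, t] = _occupied_mask(ss, L)

    # ---------------- dissociation phase
    if Td > 0:
        for side in (0, 1):
            # re-derive strands from the final association occupancy
            runs = _mask_runs(occ[side, :, Ta - 1]) if Ta > 0 else []
            strands[side] = []
            for lo, hi in runs:
                s = _Strand(lo, Ta)
                s.lo_f, s.hi_f = float(lo), float(hi)
                strands[side].append(s)
        dip_seen = [[{"lo": False, "hi": False} for _ in strands[side]] for side in (0, 1)]
        orig_ends = [[(s.lo, s.hi) for s in strands[side]] for side in (0, 1)]
        alive = [[True] * len(strands[side]) for side in (0, 1)]
        for t in range(Ta, T):
            for side in (0, 1):
                for i, s in enumerate(strands[side]):
                    if not alive[side][i]:
                        continue
                    prev_lo, prev_hi = s.lo, s.hi
                    if rng.random() < c.dissociation_end_rate:
                        if not dip_seen[side][i]["lo"]:
                            dips.append((side, orig_ends[side][i][0], t))
                            dip_seen[side][i]["lo"] = True
                        s.lo_f += 1.0
                    if s.lo_f <= s.hi_f and rng.random() < c.dissociation_end_rate:
                        if not dip_seen[side][i]["hi"]:
                            dips.append((side, orig_ends[side][i][1], t))
                            dip_seen[side][i]["hi"] = True
                        s.hi_f -= 1.0
                    if s.lo_f > s.hi_f:
                        alive[side][i] = False
                        deps.append((side, (prev_lo + prev_hi) // 2, t))
                live = [s for i, s in enumerate(strands[side]) if alive[side][i]]
                occ[side, :, t] = _occupied_mask(live, L)

    truth = GroundTruth(
        occupancy=occ,
        nucleations=nucleations,
        meetings=meetings,
        dips=dips,
        deps=deps,
        tau1_assoc=_first_frame(occ[:, :, :Ta].any(axis=0)),
        tau2_assoc=_first_frame(occ[:, :, :Ta].all(axis=0)),
        tau1_dissoc=_last_frame(occ[:, :, Ta:].any(axis=0), offset=Ta),
        tau2_dissoc=_last_frame(occ[:, :, Ta:].all(axis=0), offset=Ta),
        seed=c.seed,
        config=c,
    )

    intensity = c.background_level + c.level_step * occ.sum(axis=0).astype(float)
    if c.psf_sigma_kymo > 0:
        intensity = ndimage.gaussian_filter1d(intensity, c.psf_sigma_kymo, axis=0)
    if c.noise_sigma > 0:
        intensity = intensity + rng.normal(0.0, c.noise_sigma, size=intensity.shape)
    kymo = Kymograph(
        intensity=intensity,
        pixel_size_nm=c.pixel_size_nm,
        frame_interval_assoc_s=c.frame_interval_assoc_s,
        frame_interval_dissoc_s=c.frame_interval_dissoc_s,
        phase_boundary_index=Ta if Td > 0 else None,
        meta={"seed": c.seed},
    )
    return kymo, truth


def _mask_runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Maximal runs [lo, hi] of True values in a 1-D boolean mask."""
    runs = []
    in_run = False
    lo = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, lo = True, i
        elif not v and in_run:
            runs.append((lo, i - 1))
            in_run = False
    if in_run:
        runs.append((lo, len(mask) - 1))
    return runs


def _first_frame(mask_xt: np.ndarray) -> np.ndarray:
    """Per position: first frame index where the mask is on (NaN if never)."""
    n_pos, n_t = mask_xt.shape
    out = np.full(n_pos, np.nan)
    any_on = mask_xt.any(axis=1)
    out[any_on] = mask_xt[any_on].argmax(axis=1)
    return out


def _last_frame(mask_xt: np.ndarray, offset: int = 0) -> np.ndarray:
    n_pos, n_t = mask_xt.shape
    if n_t == 0:
        return np.full(n_pos, np.nan)
    out = np.full(n_pos, np.nan)
    any_on = mask_xt.any(axis=1)
    out[any_on] = n_t - 1 - mask_xt[any_on, ::-1].argmax(axis=1) + offset
    return out
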