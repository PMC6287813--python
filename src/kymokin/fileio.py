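"""File formats: TIFF stacks and kymographs with YAML sidecars, CSV/JSON
serialisations of boundaries, events, rates and survival tables.

Physical metadata (pixel size, frame intervals) is never defaulted silently:
reading a stack without a sidecar requires the caller to pass the values
explicitly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .boundaries import BoundarySet, Segment
from .events import Event, EventSet
from .kymo import Kymograph
from .rates import RateRecord
from .register import RigidTransform
from .stack import ImageStack
from .survival import SurvivalCurve

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


# ----------------------------------------------------------------------- stacks


def write_stack(stack: ImageStack, path: PathLike, dtype: str = "uint16") -> Path:
    """Write a stack as multi-page TIFF plus a YAML metadata sidecar.

    Default page dtype is 16-bit unsigned; values outside [0, 65535] are
    clipped with a warning.  Pass dtype='float32' to preserve values.
    """
    path = Path(path)
    data = np.asarray(stack.data)
    if dtype == "uint16":
        if data.min() < 0 or data.max() > np.iinfo(np.uint16).max:
            warnings.warn("intensities clipped to the uint16 range")
        out = np.clip(np.round(data), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype == "float32":
        out = data.astype(np.float32)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    tifffile.imwrite(path, out, photometric="minisblack")
    meta = {
        "pixel_size_nm": float(stack.pixel_size_nm),
        "frame_interval_s": float(stack.frame_interval_s),
        "frame_interval_dissoc_s": None
        if stack.frame_interval_dissoc_s is None
        else float(stack.frame_interval_dissoc_s),
        "phase_boundary_index": stack.phase_boundary_index,
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_stack(
    path: PathLike,
    pixel_size_nm: Optional[float] = None,
    frame_interval_s: Optional[float] = None,
    frame_interval_dissoc_s: Optional[float] = None,
    phase_boundary_index: Optional[int] = None,
) -> ImageStack:
    """Read a multi-page TIFF stack; metadata from the sidecar unless given.

    Supported page dtypes: 8/16-bit unsigned and 32/64-bit float.  Page
    values are preserved exactly (no rescaling).
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"expected a stack of 2-D pages; got shape {data.shape}")
    if data.dtype not in (np.uint8, np.uint16, np.float32, np.float64):
        raise ValueError(f"unsupported dtype {data.dtype}")
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = yaml.safe_load(sc.read_text()) or {}
    pixel_size_nm = pixel_size_nm if pixel_size_nm is not None else meta.get("pixel_size_nm")
    frame_interval_s = (
        frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s")
    )
    if pixel_size_nm is None or frame_interval_s is None:
        raise ValueError(
            f"missing physical metadata for {path}: provide pixel_size_nm and "
            "frame_interval_s explicitly or in the YAML sidecar"
        )
    if frame_interval_dissoc_s is None:
        frame_interval_dissoc_s = meta.get("frame_interval_dissoc_s")
    if phase_boundary_index is None:
        phase_boundary_index = meta.get("phase_boundary_index")
    return ImageStack(
        data=data,
        pixel_size_nm=float(pixel_size_nm),
        frame_interval_s=float(frame_interval_s),
        frame_interval_dissoc_s=None
        if frame_interval_dissoc_s is None
        else float(frame_interval_dissoc_s),
        phase_boundary_index=phase_boundary_index,
    )


# ------------------------------------------------------------------- kymographs


def write_kymograph(kymo: Kymograph, path: PathLike) -> Path:
    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_nm": float(kymo.pixel_size_nm),
        "frame_interval_assoc_s": float(kymo.frame_interval_assoc_s),
        "frame_interval_dissoc_s": None
        if kymo.frame_interval_dissoc_s is None
        else float(kymo.frame_interval_dissoc_s),
        "phase_boundary_index": kymo.phase_boundary_index,
        "averaging_width": int(kymo.averaging_width),
        "source_path": None
        if kymo.source_path is None
        else [list(map(float, p)) for p in kymo.source_path],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_kymograph(path: PathLike) -> Kymograph:
    path = Path(path)
    intensity = tifffile.imread(path)
    sc = _sidecar(path)
    if not sc.exists():
        raise ValueError(f"kymograph sidecar {sc} not found")
    meta = yaml.safe_load(sc.read_text()) or {}
    if "pixel_size_nm" not in meta or "frame_interval_assoc_s" not in meta:
        raise ValueError(f"kymograph sidecar {sc} lacks physical metadata")
    return Kymograph(
        intensity=np.asarray(intensity, dtype=float),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        frame_interval_assoc_s=float(meta["frame_interval_assoc_s"]),
        frame_interval_dissoc_s=None
        if meta.get("frame_interval_dissoc_s") is None
        else float(meta["frame_interval_dissoc_s"]),
        phase_boundary_index=meta.get("phase_boundary_index"),
        source_path=None
        if meta.get("source_path") is None
        else tuple(tuple(p) for p in meta["source_path"]),
        averaging_width=int(meta.get("averaging_width", 1)),
    )


def kymograph_to_csv(kymo: Kymograph, path: PathLike) -> Path:
    """Long-format CSV export: position, frame, intensity."""
    path = Path(path)
    pos, frame = np.meshgrid(
        np.arange(kymo.n_positions), np.arange(kymo.n_frames), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "position": pos.ravel(),
            "frame": frame.ravel(),
            "intensity": kymo.intensity.ravel(),
        }
    )
    df.to_csv(path, index=False)
    return path


# ------------------------------------------------------------------- boundaries


def _segment_to_dict(s: Segment) -> dict:
    return {
        "seg_id": int(s.seg_id),
        "level": int(s.level),
        "side": s.side,
        "vertices": [[float(a), float(b)] for a, b in s.vertices],
    }


def _segment_from_dict(d: dict) -> Segment:
    return Segment(
        seg_id=int(d["seg_id"]),
        vertices=np.array(d["vertices"], dtype=float).reshape(-1, 2),
        level=int(d["level"]),
        side=d.get("side", "unassigned"),
    )


def write_boundaries(b: BoundarySet, path: PathLike) -> Path:
    path = Path(path)
    payload = {
        "phase": b.phase,
        "frame_range": list(b.frame_range),
        "tau_outer": [None if not np.isfinite(v) else float(v) for v in b.tau_outer],
        "tau_inner": [None if not np.isfinite(v) else float(v) for v in b.tau_inner],
        "segments": [_segment_to_dict(s) for s in b.segments],
        "raw_segments": [_segment_to_dict(s) for s in b.raw_segments],
        "edit_log": b.edit_log,
        "masked_ranges": [list(r) for r in b.masked_ranges],
        "meta": {k: v for k, v in b.meta.items() if isinstance(v, (int, float, str))},
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_boundaries(path: PathLike) -> BoundarySet:
    d = json.loads(Path(path).read_text())
    to_arr = lambda xs: np.array([np.nan if v is None else v for v in xs], dtype=float)
    return BoundarySet(
        tau_outer=to_arr(d["tau_outer"]),
        tau_inner=to_arr(d["tau_inner"]),
        phase=d["phase"],
        frame_range=tuple(d["frame_range"]),
        segments=[_segment_from_dict(s) for s in d["segments"]],
        raw_segments=[_segment_from_dict(s) for s in d["raw_segments"]],
        edit_log=list(d.get("edit_log", [])),
        masked_ranges=[tuple(r) for r in d.get("masked_ranges", [])],
        meta=d.get("meta", {}),
    )


def boundaries_tau_csv(b: BoundarySet, path: PathLike) -> Path:
    df = pd.DataFrame(
        {
            "position": np.arange(b.tau_outer.size),
            "tau_outer_frame": b.tau_outer,
            "tau_inner_frame": b.tau_inner,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


# ----------------------------------------------------------- events and results


def write_events(events: EventSet, path: PathLike) -> Path:
    rows = [
        {
            "kind": e.kind,
            "position": e.position,
            "time_frames": e.time,
            "segment_id": e.segment_id,
            "label": e.label,
        }
        for e in events.all_events() + events.user_marks
    ]
    pd.DataFrame(rows, columns=["kind", "position", "time_frames", "segment_id", "label"]).to_csv(
        path, index=False
    )
    return Path(path)


def read_events(path: PathLike) -> EventSet:
    df = pd.read_csv(Path(path), keep_default_na=False)
    es = EventSet()
    buckets = {
        "nucleation": es.nucleations,
        "meeting": es.meetings,
        "dip": es.dips,
        "dep": es.deps,
        "user": es.user_marks,
    }
    for _, row in df.iterrows():
        buckets[row["kind"]].append(
            Event(
                position=int(row["position"]),
                time=float(row["time_frames"]),
                segment_id=int(row["segment_id"]),
                kind=row["kind"],
                label=str(row.get("label", "") or ""),
            )
        )
    return es


def write_rates(records: Sequence[RateRecord], path: PathLike) -> Path:
    rows = [
        {
            "side": r.side,
            "phase": r.phase,
            "direction": r.direction,
            "rate_px_per_frame": r.rate_px_per_frame,
            "rate_nm_per_s": r.rate_nm_per_s,
            "weight_px": r.weight,
            "segment_id": r.segment_id,
            "below_cutoff": r.below_cutoff,
        }
        for r in records
    ]
    cols = [
        "side",
        "phase",
        "direction",
        "rate_px_per_frame",
        "rate_nm_per_s",
        "weight_px",
        "segment_id",
        "below_cutoff",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)
    return Path(path)


def write_survival(curve: SurvivalCurve, path: PathLike) -> Path:
    df = pd.DataFrame(
        {
            "frame": curve.times.astype(int),
            "time_s": curve.times * curve.frame_interval_s,
            "d": curve.d,
            "n": curve.n,
            "S": curve.S,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)


# ------------------------------------------------------------------- transforms


def write_transform(t: RigidTransform, path: PathLike) -> Path:
    payload = {
        "rotation_deg": float(t.rotation_deg),
        "translation_row": float(t.translation_row),
        "translation_col": float(t.translation_col),
        "center": [float(t.center[0]), float(t.center[1])],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
    return Path(path)


def read_transform(path: PathLike) -> RigidTransform:
    d = yaml.safe_load(Path(path).read_text())
    return RigidTransform(
        rotation_deg=float(d["rotation_deg"]),
        translation_row=float(d["translation_row"]),
        translation_col=float(d["translation_col"]),
        center=tuple(d["center"]),
    )
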