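"""End-to-end orchestration: register -> concatenate -> kymograph -> detect ->
(scripted edits) -> events -> rates -> survival, with a machine-readable run
manifest.

Every stage logs its counts; a stage failure aborts the run with the stage
name while keeping the outputs written so far.  Re-running with an identical
configuration and seed reproduces the output files byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import fileio
from .boundaries import ThresholdSettings, auto_thresholds, detect_boundaries, edit_boundaries
from .events import ExtremaSettings, detect_all
from .kymo import extract_kymograph
from .rates import rates_from_events
from .register import RegistrationSettings, RigidTransform, concatenate_phases, register_rigid
from .survival import (
    UnidentifiableNucleationTime,
    available_sites,
    fit_nucleation_time,
    km_estimator,
    occupancy_from_boundaries,
)

log = logging.getLogger("kymokin")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either both ``assoc_path``/``dissoc_path`` (registered and concatenated)
    or a single ``merged_path`` must be given.  Path endpoints are (row, col)
    pixel coordinates of the straight filament backbone.
    """

    out_dir: str
    assoc_path: Optional[str] = None
    dissoc_path: Optional[str] = None
    merged_path: Optional[str] = None
    path_p0: tuple = (0, 0)
    path_p1: tuple = (0, 1)
    path_width: int = 1
    pixel_size_nm: Optional[float] = None
    frame_interval_assoc_s: Optional[float] = None
    frame_interval_dissoc_s: Optional[float] = None
    feed_concentration_nM: Optional[float] = None
    low_threshold: Optional[float] = None
    high_threshold: Optional[float] = None
    median_window: tuple = (3, 3)
    structuring_element: tuple = ("disk", 2)
    extrema: ExtremaSettings = field(default_factory=ExtremaSettings)
    registration: RegistrationSettings = field(default_factory=RegistrationSettings)
    edits_script: Optional[str] = None  # YAML list of edit ops, applied to assoc
    polarity: Optional[str] = None  # 'p0-barbed' | 'p0-pointed'
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float, str, tuple, list, type(None)))
        }
        d["median_window"] = list(self.median_window)
        d["structuring_element"] = list(self.structuring_element)
        d["path_p0"], d["path_p1"] = list(self.path_p0), list(self.path_p1)
        return d


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "stages": [],
        "counts": {},
        "outputs": {},
    }

    def done(stage: str, **counts) -> None:
        manifest["stages"].append(stage)
        manifest["counts"].update(counts)
        log.info("stage %s done %s", stage, counts or "")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    stage = "register"
    try:
        if config.merged_path is not None:
            merged = fileio.read_stack(
                config.merged_path,
                pixel_size_nm=config.pixel_size_nm,
                frame_interval_s=config.frame_interval_assoc_s,
                frame_interval_dissoc_s=config.frame_interval_dissoc_s,
            )
            transform = RigidTransform()
            done("register", registration="skipped (merged input)")
            done("concatenate")
        else:
            if config.assoc_path is None or config.dissoc_path is None:
                raise ValueError("need merged_path or both assoc_path and dissoc_path")
            assoc = fileio.read_stack(
                config.assoc_path,
                pixel_size_nm=config.pixel_size_nm,
                frame_interval_s=config.frame_interval_assoc_s,
            )
            dissoc = fileio.read_stack(
                config.dissoc_path,
                pixel_size_nm=config.pixel_size_nm,
                frame_interval_s=config.frame_interval_dissoc_s,
            )
            transform, metric = register_rigid(
                assoc.data[-1], dissoc.data[0], config.registration
            )
            fileio.write_transform(transform, out / "transform.yaml")
            manifest["outputs"]["transform"] = "transform.yaml"
            done("register", registration_metric=metric)
            stage = "concatenate"
            merged = concatenate_phases(assoc, dissoc, transform)
            done("concatenate", n_frames=merged.n_frames)

        stage = "kymograph"
        kym = extract_kymograph(merged, config.path_p0, config.path_p1, config.path_width)
        fileio.write_kymograph(kym, out / "kymo.tif")
        manifest["outputs"]["kymograph"] = "kymo.tif"
        done("kymograph", n_positions=kym.n_positions)

        stage = "detect"
        if config.low_threshold is None or config.high_threshold is None:
            low, high = auto_thresholds(kym)
        else:
            low, high = config.low_threshold, config.high_threshold
        settings = ThresholdSettings(
            low_threshold=low,
            high_threshold=high,
            median_window=tuple(config.median_window),
            structuring_element=tuple(config.structuring_element),
        )
        settings_meta = {
            "pixel_size_nm": kym.pixel_size_nm,
            "frame_interval_s": kym.frame_interval_assoc_s,
        }
        b_assoc = detect_boundaries(kym, settings, phase="association")
        b_assoc.meta.update(settings_meta)
        bounds = {"association": b_assoc}
        if kym.phase_boundary_index is not None:
            b_dis = detect_boundaries(kym, settings, phase="dissociation")
            b_dis.meta.update(
                {**settings_meta, "frame_interval_s": kym.frame_interval_dissoc_s
                 or kym.frame_interval_assoc_s}
            )
            bounds["dissociation"] = b_dis
        n_segs = sum(len(b.segments) for b in bounds.values())
        done("detect", n_segments=n_segs, low_threshold=low, high_threshold=high)

        stage = "edit"
        if config.edits_script is not None:
            ops = yaml.safe_load(Path(config.edits_script).read_text()) or []
            bounds["association"] = edit_boundaries(bounds["association"], ops)
            done("edit", n_edits=len(ops))
        else:
            done("edit", n_edits=0)
        for phase, b in bounds.items():
            fileio.write_boundaries(b, out / f"bounds_{phase}.json")
            manifest["outputs"][f"bounds_{phase}"] = f"bounds_{phase}.json"

        stage = "events"
        event_sets = {phase: detect_all(b, config.extrema) for phase, b in bounds.items()}
        all_counts = {}
        for phase, es in event_sets.items():
            fileio.write_events(es, out / f"events_{phase}.csv")
            manifest["outputs"][f"events_{phase}"] = f"events_{phase}.csv"
            all_counts[f"nucleations_{phase}"] = len(es.nucleations)
            all_counts[f"meetings_{phase}"] = len(es.meetings)
            all_counts[f"dips_{phase}"] = len(es.dips)
            all_counts[f"deps_{phase}"] = len(es.deps)
        done("events", **all_counts)

        stage = "rates"
        records = []
        for phase, b in bounds.items():
            records.extend(
                rates_from_events(b, event_sets[phase], polarity=config.polarity)
            )
        fileio.write_rates(records, out / "rates.csv")
        manifest["outputs"]["rates"] = "rates.csv"
        done("rates", n_rate_records=len(records))

        stage = "survival"
        b = bounds["association"]
        occ = occupancy_from_boundaries(b.tau_outer, b.frame_range)
        n_series = available_sites(occ)
        start = b.frame_range[0]
        ev_frames = [
            int(round(e.time)) - start for e in event_sets["association"].nucleations
        ]
        end_frame = b.frame_range[1] - start
        curve = km_estimator(
            ev_frames, n_series, end_frame, frame_interval_s=kym.frame_interval_assoc_s
        )
        fileio.write_survival(curve, out / "survival.csv")
        manifest["outputs"]["survival"] = "survival.csv"
        try:
            fit = fit_nucleation_time(curve)
            report = {
                "t_nuc_s": fit.t_nuc_s,
                "fit_rss": fit.fit_rss,
                "n_events": fit.n_events,
                "censored": fit.censored,
            }
        except UnidentifiableNucleationTime as err:
            report = {"t_nuc_s": None, "lower_bound_s": err.lower_bound_s, "n_events": 0}
        (out / "tnuc.yaml").write_text(yaml.safe_dump(report, sort_keys=True))
        manifest["outputs"]["nucleation_time"] = "tnuc.yaml"
        done("survival", **{k: v for k, v in report.items() if v is not None})
    except Exception as err:
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return manifest
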