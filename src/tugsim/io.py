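"""Plain-text I/O and the end-to-end pipeline.

Tracks travel as comma-separated tables with columns ``track_id, t_s, x_nm``
(extra columns are preserved as per-sample channels), the format produced by
common particle-tracking exports.  Segment tables, statistics JSON and a
run manifest (config hash, seeds, version) make every pipeline output
regenerable from its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .motors import MotorParams, SchnitzerParams, ddb_params, kif16b_params
from .segmentation import AnnealConfig, segment_track
from .simulate import SimConfig, Track, simulate_cargoes
from .stats import (
    classify_track,
    spatial_pause_frequency,
)

log = logging.getLogger("tugsim")

__all__ = [
    "read_tracks",
    "write_tracks",
    "write_segments",
    "load_motor_params",
    "load_sim_config",
    "load_anneal_config",
    "PipelineConfig",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("track_id", "t_s", "x_nm")


def read_tracks(path) -> list[Track]:
    """Read a track table; one :class:`Track` per id, time-sorted.

    Raises on missing columns, non-numeric cells, duplicate (id, t) pairs
    and non-uniform sampling, naming the offending track.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in df.columns:
        if col == "track_id":
            continue
        df[col] = pd.to_numeric(df[col], errors="raise")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("t_s")
        t = grp["t_s"].to_numpy(float)
        if len(t) > 1 and np.any(np.diff(t) == 0):
            raise ValueError(f"track {tid}: duplicate time points")
        extras = {
            c: grp[c].to_numpy()
            for c in grp.columns
            if c not in REQUIRED_COLUMNS
        }
        try:
            tracks.append(Track(str(tid), t, grp["x_nm"].to_numpy(float), extras))
        except ValueError as err:
            raise ValueError(f"track {tid}: {err}") from err
    return tracks


def write_tracks(tracks: list[Track], path) -> None:
    if tracks:
        df = pd.concat([tr.to_frame() for tr in tracks], ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    df.to_csv(path, index=False, float_format="%.10g")


def write_segments(results: dict, path) -> None:
    """Segment table for a mapping track_id -> SegmentationResult."""
    frames = []
    for tid, res in results.items():
        df = res.summary()
        df.insert(0, "track_id", tid)
        frames.append(df)
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["track_id", "seg_index", "kind"])
    )
    out.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# YAML configuration


def _dataclass_from_mapping(cls, mapping, name):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - fields
    if unknown:
        raise ValueError(f"{name}: unknown key(s) {sorted(unknown)}")
    return mapping


def load_motor_params(mapping: dict, species: str) -> MotorParams:
    """MotorParams from a config mapping, on top of the species defaults."""
    base = ddb_params() if species.upper() == "DDB" else kif16b_params()
    mapping = dict(mapping or {})
    sch = mapping.pop("schnitzer", None)
    if sch is not None:
        mapping["schnitzer"] = SchnitzerParams(
            **_dataclass_from_mapping(SchnitzerParams, sch, "schnitzer")
        )
    return base.replace(**_dataclass_from_mapping(MotorParams, mapping, species))


def load_sim_config(mapping: dict) -> SimConfig:
    mapping = dict(mapping or {})
    if "fixed_counts" in mapping and mapping["fixed_counts"] is not None:
        mapping["fixed_counts"] = tuple(mapping["fixed_counts"])
    return SimConfig(**_dataclass_from_mapping(SimConfig, mapping, "simulation"))


def load_anneal_config(mapping: dict) -> AnnealConfig:
    return AnnealConfig(
        **_dataclass_from_mapping(AnnealConfig, dict(mapping or {}), "segmentation")
    )


def load_config(path):
    """Parse a YAML file with optional sections motors.DDB, motors.KIF16B,
    simulation, segmentation."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    motors = raw.get("motors", {})
    return dict(
        ddb=load_motor_params(motors.get("DDB", {}), "DDB"),
        kif=load_motor_params(motors.get("KIF16B", {}), "KIF16B"),
        sim=load_sim_config(raw.get("simulation", {})),
        anneal=load_anneal_config(raw.get("segmentation", {})),
        raw=raw,
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclasses.dataclass
class PipelineConfig:
    """simulate (optional) -> segment -> classify -> stats."""

    out_dir: str
    seed: int = 0
    simulate: bool = True
    n_cargoes: int = 50
    tracks_path: str | None = None  # consumed instead of simulating
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    ddb: MotorParams = dataclasses.field(default_factory=ddb_params)
    kif: MotorParams = dataclasses.field(default_factory=kif16b_params)
    anneal: AnnealConfig = dataclasses.field(default_factory=AnnealConfig)


def _seed_for_track(global_seed: int, track_id: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{track_id}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def summarize_tracks(tracks, results) -> dict:
    """Classification counts, velocity summaries and pause statistics."""
    labels = {}
    run_vel_pos, run_vel_neg, pause_durs = [], [], []
    pause_dist = []
    for tr in tracks:
        res = results[tr.track_id]
        cls = classify_track(res.segments)
        labels[tr.track_id] = cls.label
        for seg in res.segments:
            if seg.kind == "run_pos":
                run_vel_pos.append(seg.mean_velocity)
            elif seg.kind == "run_neg":
                run_vel_neg.append(seg.mean_velocity)
            else:
                pause_durs.append(seg.duration)
        dist_um = (
            sum(abs(s.distance) for s in res.segments if s.is_run) / 1000.0
        )
        if dist_um > 0:
            pause_dist.append((cls.n_pauses, dist_um))
    counts = {
        lab: sum(1 for v in labels.values() if v == lab)
        for lab in ("minus", "plus", "reversal", "stationary")
    }

    def _med_iqr(vals):
        if not vals:
            return None
        q1, q2, q3 = np.percentile(vals, [25, 50, 75])
        return dict(median=float(q2), iqr=float(q3 - q1), n=len(vals))

    out = dict(
        n_tracks=len(tracks),
        class_counts=counts,
        class_fractions={
            k: v / len(tracks) if tracks else 0.0 for k, v in counts.items()
        },
        run_velocity_pos_nm_s=_med_iqr(run_vel_pos),
        run_velocity_neg_nm_s=_med_iqr(run_vel_neg),
        pause_duration_s=_med_iqr(pause_durs),
        track_labels=labels,
    )
    if pause_dist:
        pf = spatial_pause_frequency(pause_dist)
        out["pause_frequency_per_um"] = dict(
            weighted_mean=pf.weighted_mean,
            weighted_sd=pf.weighted_sd,
            weighted_sem=pf.weighted_sem,
            n_tracks=pf.n_tracks,
        )
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the pipeline and write tracks.csv, segments.csv, stats.json
    and manifest.json into ``config.out_dir``.  Deterministic under a fixed
    seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        log.info("simulating %d cargoes", config.n_cargoes)
        tracks = simulate_cargoes(
            config.sim,
            config.n_cargoes,
            seed=config.seed,
            ddb=config.ddb,
            kif=config.kif,
        )
    else:
        if not config.tracks_path:
            raise ValueError("tracks_path required when simulate=False")
        tracks = read_tracks(config.tracks_path)
    write_tracks(tracks, out / "tracks.csv")

    results = {}
    for tr in tracks:
        try:
            results[tr.track_id] = segment_track(
                tr, config.anneal, seed=_seed_for_track(config.seed, tr.track_id)
            )
        except Exception as err:  # noqa: BLE001 - annotate failing stage
            raise RuntimeError(
                f"segmentation failed for track {tr.track_id}: {err}"
            ) from err
        log.debug("segmented %s", tr.track_id)
    write_segments(results, out / "segments.csv")

    summary = summarize_tracks(tracks, results)
    with open(out / "stats.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    manifest = dict(
        version=__version__,
        seed=config.seed,
        simulate=config.simulate,
        n_cargoes=config.n_cargoes if config.simulate else None,
        tracks_path=config.tracks_path,
        sim_config_hash=config.sim.hash(),
        outputs=["tracks.csv", "segments.csv", "stats.json"],
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
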