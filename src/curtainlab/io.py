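"""File formats: uncompressed 16-bit TIFF stacks, trajectory CSV tables,
BED-like roadblock annotations, YAML run configs and JSON reports.

Trajectory tables are plain CSV (desk-scale data, inspectable in any
editor) with a declared schema; every writer embeds a format version and,
where available, the run seed and a config hash for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import DnaGeometry
from .obstacles import Roadblock
from .tracking import Trajectory

FORMAT_VERSION = 1

TRAJECTORY_COLUMNS = [
    "molecule_id",
    "dna_axis_id",
    "frame",
    "time_s",
    "position_um",
    "position_bp",
    "lateral_um",
    "detected",
]


def read_tiff_stack(path) -> np.ndarray:
    """Read an uncompressed grayscale TIFF movie as (frames, y, x).

    Multichannel (RGB) pages are an unsupported dialect and raise; a
    truncated file raises naming the failing page.
    """
    path = Path(path)
    # tifffile silently drops pages whose offsets are broken (truncated
    # files), logging an error instead of raising; watch its logger
    errors: list = []
    handler = logging.Handler()
    handler.emit = lambda record: errors.append(record)  # type: ignore[assignment]
    handler.setLevel(logging.ERROR)
    tiff_logger = logging.getLogger("tifffile")
    tiff_logger.addHandler(handler)
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.pages
            frames = []
            shape = None
            for i, page in enumerate(pages):
                try:
                    arr = page.asarray()
                except Exception as exc:
                    raise IOError(
                        f"corrupt TIFF: failed to read page {i} of {path}"
                    ) from exc
                if arr.ndim != 2:
                    raise ValueError(
                        f"unsupported TIFF dialect: page {i} is not single-channel grayscale"
                    )
                if shape is None:
                    shape = arr.shape
                elif arr.shape != shape:
                    raise ValueError(f"page {i} shape {arr.shape} differs from {shape}")
                frames.append(arr)
    finally:
        tiff_logger.removeHandler(handler)
    if errors:
        raise IOError(
            f"corrupt TIFF {path}: {errors[0].getMessage()} "
            f"(read {len(frames)} page(s) before the damage)"
        )
    if not frames:
        raise ValueError(f"empty TIFF: {path}")
    return np.stack(frames)


def write_tiff_stack(path, stack: np.ndarray) -> None:
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, y, x)")
    tifffile.imwrite(path, stack.astype(np.uint16), compression=None)


def trajectories_to_table(
    tracks: Sequence[Trajectory], geometry: Optional[DnaGeometry] = None
) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        geo = tr.geometry or geometry
        frames = np.round(tr.times_s / tr.frame_interval_s).astype(int)
        for k in range(len(tr.times_s)):
            det = bool(tr.detected[k])
            rows.append(
                {
                    "molecule_id": tr.molecule_id,
                    "dna_axis_id": tr.dna_axis_id,
                    "frame": int(frames[k]),
                    "time_s": float(tr.times_s[k]),
                    "position_um": float(tr.positions_um[k]) if det else np.nan,
                    "position_bp": float(geo.um_to_bp(tr.positions_um[k]))
                    if det and geo is not None
                    else np.nan,
                    "lateral_um": float(tr.lateral_um[k])
                    if det and tr.lateral_um is not None
                    else np.nan,
                    "detected": int(det),
                }
            )
    return pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS)


def validate_trajectory_table(df: pd.DataFrame) -> None:
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trajectory table is missing columns: {missing}")
    if df.duplicated(subset=["molecule_id", "frame"]).any():
        raise ValueError("duplicated (molecule_id, frame) rows")


def write_trajectories(
    path,
    tracks: Sequence[Trajectory],
    geometry: Optional[DnaGeometry] = None,
) -> None:
    df = trajectories_to_table(tracks, geometry)
    validate_trajectory_table(df)
    with open(path, "w") as fh:
        fh.write(f"# curtainlab trajectory table v{FORMAT_VERSION}\n")
        df.to_csv(fh, index=False)


def read_trajectories(
    path,
    frame_interval_s: float = 0.2,
    geometry: Optional[DnaGeometry] = None,
) -> List[Trajectory]:
    df = pd.read_csv(path, comment="#")
    validate_trajectory_table(df)
    tracks = []
    for mid, grp in df.groupby("molecule_id"):
        grp = grp.sort_values("frame")
        det = grp["detected"].to_numpy(dtype=bool)
        pos = grp["position_um"].to_numpy(dtype=float)
        # undetected rows carry no position; interpolate to keep grid aligned
        if det.any() and not det.all():
            idx = np.arange(len(pos))
            pos = np.interp(idx, idx[det], pos[det])
        lat = grp["lateral_um"].to_numpy(dtype=float)
        tracks.append(
            Trajectory(
                molecule_id=int(mid),
                frame_interval_s=frame_interval_s,
                times_s=grp["time_s"].to_numpy(dtype=float),
                positions_um=pos,
                detected=det,
                lateral_um=lat if np.isfinite(lat).any() else None,
                dna_axis_id=str(grp["dna_axis_id"].iloc[0]),
                geometry=geometry,
            )
        )
    return tracks


def read_roadblocks(path) -> List[Roadblock]:
    """BED-like TSV: dna_axis_id, start_bp, end_bp, kind[, permeability]."""
    blocks = []
    with open(path) as fh:
        for ln, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"line {ln + 1}: need >= 4 tab-separated fields")
            axis, start, end, kind = parts[:4]
            start, end = float(start), float(end)
            perm = float(parts[4]) if len(parts) > 4 else 1.0
            blocks.append(
                Roadblock(
                    position_bp=(start + end) / 2.0,
                    id=f"{kind}_{ln}",
                    dna_axis_id=axis,
                    kind=kind,
                    permeability=perm,
                )
            )
    return blocks


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_report(path, report: dict, cfg: Optional[dict] = None, seed: Optional[int] = None) -> None:
    out = {"format_version": FORMAT_VERSION}
    if cfg is not None:
        out["config"] = cfg
        out["config_hash"] = config_hash(cfg)
    if seed is not None:
        out["seed"] = seed
    out.update(report)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
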