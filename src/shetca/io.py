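"""CSV / PNG readers and writers, configuration, and run manifests.

Integration-matrix dialect: comma-separated UTF-8, first column the
fraction id, header row the compound ids.  A MISSING cell (compound not
detected in that fraction) is an EMPTY cell, never "0" -- an explicit 0 is
a measured zero and enters the sparse-heterocovariance statistics, so the
distinction is preserved exactly through round trips.  Reading a matrix
that contains explicit zeros emits a warning rather than an error.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from shetca.densitometry import Channel, Densitogram, Illumination, Phase, TrackGeometry


# ---------------------------------------------------------------------------
# Integration matrix


def write_integration_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, na_rep="")


def read_integration_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col=0)
    matrix.index = matrix.index.astype(str)
    for col in matrix.columns:
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        new_na = coerced.isna() & matrix[col].notna()
        if new_na.any():
            row = new_na[new_na].index[0]
            raise ValueError(
                f"non-numeric cell {matrix.loc[row, col]!r} at row {row!r}, "
                f"column {col!r}"
            )
        matrix[col] = coerced
    if (matrix == 0).any().any():
        warnings.warn(
            "integration matrix contains explicit zeros; they count as "
            "measured values in sHetCA (empty cells mean not-detected)",
            stacklevel=2,
        )
    return matrix


# ---------------------------------------------------------------------------
# Activity vector


def write_activity(activity: pd.Series, path) -> None:
    frame = activity.rename("activity").to_frame()
    frame.index.name = "fraction"
    frame.to_csv(path)


def read_activity(path) -> pd.Series:
    frame = pd.read_csv(path, index_col=0)
    if "activity" not in frame.columns:
        raise ValueError(f"{path}: expected an 'activity' column")
    series = pd.to_numeric(frame["activity"], errors="raise")
    series.index = series.index.astype(str)
    return series


# ---------------------------------------------------------------------------
# Densitograms: one row per track, first column sample_id, rf-value header


def write_densitograms(densitograms: list[Densitogram], path, sidecar: bool = True) -> None:
    rf = densitograms[0].rf
    rows = {d.sample_id: d.intensity for d in densitograms}
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=np.round(rf, 6))
    frame.index.name = "sample_id"
    frame.to_csv(path)
    if sidecar:
        d = densitograms[0]
        meta = {
            "illumination": d.illumination.value if d.illumination else None,
            "phase": d.phase.value if d.phase else None,
            "channel": d.channel_used.value if d.channel_used else None,
            "n_points": int(rf.size),
        }
        Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_densitograms(path) -> list[Densitogram]:
    frame = pd.read_csv(path, index_col=0)
    rf = frame.columns.to_numpy(dtype=float)
    meta_path = Path(str(path) + ".meta.yaml")
    illumination = phase = channel = None
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text())
        illumination = Illumination(meta["illumination"]) if meta.get("illumination") else None
        phase = Phase(meta["phase"]) if meta.get("phase") else None
        channel = Channel(meta["channel"]) if meta.get("channel") else None
    return [
        Densitogram(
            rf=rf,
            intensity=frame.loc[sid].to_numpy(dtype=float),
            sample_id=str(sid),
            illumination=illumination,
            phase=phase,
            channel_used=channel,
        )
        for sid in frame.index
    ]


# ---------------------------------------------------------------------------
# Plate images


def write_plate_image(pixels: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8), mode="RGB").save(path)


def read_plate_image(path) -> np.ndarray:
    with Image.open(path) as img:
        return np.asarray(img.convert("RGB"))


# ---------------------------------------------------------------------------
# Geometry / pipeline configuration (flat key-value YAML)


def read_geometry(path) -> TrackGeometry:
    raw = yaml.safe_load(Path(path).read_text())
    known = {
        "application_distance_mm",
        "solvent_front_mm",
        "tracks",
        "band_width_mm",
        "edge_trim_mm",
        "pixels_per_mm",
        "plate_height_mm",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown geometry keys: {sorted(unknown)}")
    tracks = raw.pop("tracks")
    return TrackGeometry(track_center_x_mm=tracks, **raw)


def write_geometry(geometry: TrackGeometry, path) -> None:
    data = {
        "application_distance_mm": geometry.application_distance_mm,
        "solvent_front_mm": geometry.solvent_front_mm,
        "tracks": list(geometry.track_center_x_mm),
        "band_width_mm": geometry.band_width_mm,
        "edge_trim_mm": geometry.edge_trim_mm,
        "pixels_per_mm": geometry.pixels_per_mm,
        "plate_height_mm": geometry.plate_height_mm,
    }
    Path(path).write_text(yaml.safe_dump(data))


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    command: str
    parameters: dict
    inputs: dict = field(default_factory=dict)   # path -> sha256
    outputs: dict = field(default_factory=dict)
    record_counts: dict = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""


def _digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir,
    command: str,
    parameters: dict,
    inputs: list | None = None,
    outputs: list | None = None,
    record_counts: dict | None = None,
) -> Path:
    from shetca import __version__

    manifest = RunManifest(
        command=command,
        parameters={k: (v.value if hasattr(v, "value") else v) for k, v in parameters.items()},
        inputs={str(p): _digest(p) for p in (inputs or []) if Path(p).exists()},
        outputs={str(p): _digest(p) for p in (outputs or []) if Path(p).exists()},
        record_counts=record_counts or {},
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    path = Path(out_dir) / f"manifest_{command}.json"
    path.write_text(json.dumps(manifest.__dict__, indent=2, default=str))
    return path
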