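"""Readers/writers for every on-disk artifact.

Formats: multi-page TIFF for label / intensity / probability movies, CSV
for track, feature, event and flag tables, JSON (canonical) or flat CSV
for edit scripts, YAML for run configuration.  Readers reject rather than
coerce on integrity violations; every writer/reader pair round-trips
losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import LabelMovie
from .errors import GeometryError, IntegrityError, MovieFormatError, ScriptError

__all__ = [
    "read_label_movie",
    "write_label_movie",
    "read_intensity_movie",
    "write_intensity_movie",
    "read_probability_movie",
    "write_probability_movie",
    "read_track_csv",
    "write_track_csv",
    "read_event_csv",
    "write_event_csv",
    "read_edit_script",
    "write_edit_script",
    "read_config",
    "TRACK_COLUMNS",
    "EVENT_COLUMNS",
]

TRACK_COLUMNS = ["track_id", "frame", "label", "y", "x", "area",
                 "parent_track", "touches_border"]
EVENT_COLUMNS = ["event_id", "kind", "frame", "y", "x", "parent_track",
                 "daughter_a", "daughter_b"]

#: default column aliases for third-party track tables (TrackMate-style
#: names included); extended via the ``column_aliases`` config section.
DEFAULT_TRACK_ALIASES = {
    "track_id": ["track_id", "TRACK_ID", "TrackID", "track"],
    "frame": ["frame", "FRAME", "t", "POSITION_T"],
    "label": ["label", "LABEL", "cell_id", "id"],
    "y": ["y", "POSITION_Y", "centroid_y"],
    "x": ["x", "POSITION_X", "centroid_x"],
    "area": ["area", "AREA"],
    "parent_track": ["parent_track", "parent", "PARENT_TRACK"],
    "touches_border": ["touches_border"],
}


def _as_movie_array(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise MovieFormatError(
            f"{path}: expected T x Y x X pages, got shape {arr.shape} "
            "(channels unsupported)")
    return arr


def read_label_movie(path: str | Path, pixel_size: float = 1.0,
                     frame_interval: float = 1.0) -> LabelMovie:
    """Read a multi-page TIFF as a label movie (single image -> T=1)."""
    arr = _as_movie_array(path)
    if not np.issubdtype(arr.dtype, np.integer):
        raise MovieFormatError(
            f"{path}: label movie must be integer-typed, got {arr.dtype}")
    return LabelMovie(arr, pixel_size=pixel_size, frame_interval=frame_interval)


def write_label_movie(movie: LabelMovie, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), movie.data, photometric="minisblack")


def read_intensity_movie(path: str | Path) -> np.ndarray:
    """Raw intensity movie, any numeric dtype, returned as float32."""
    return _as_movie_array(path).astype(np.float32)


def write_intensity_movie(arr: np.ndarray, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), np.asarray(arr, dtype=np.float32),
                     photometric="minisblack")


def read_probability_movie(path: str | Path,
                           like: LabelMovie | None = None,
                           tol: float = 1e-6) -> np.ndarray:
    """Float movie of per-pixel event probabilities in [0, 1].

    If ``like`` is given, the geometry must match exactly -- a mismatch is
    an error, never a silent resample.
    """
    arr = _as_movie_array(path).astype(np.float64)
    if arr.min() < -tol or arr.max() > 1 + tol:
        raise MovieFormatError(
            f"{path}: probability values outside [0, 1] "
            f"(range [{arr.min():g}, {arr.max():g}])")
    arr = np.clip(arr, 0.0, 1.0)
    if like is not None and arr.shape != like.data.shape:
        raise GeometryError(
            f"{path}: probability movie shape {arr.shape} != label movie "
            f"shape {like.data.shape}")
    return arr


def write_probability_movie(arr: np.ndarray, path: str | Path) -> None:
    a = np.asarray(arr, dtype=np.float32)
    if a.min() < 0 or a.max() > 1:
        raise MovieFormatError("probability values outside [0, 1]")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), a, photometric="minisblack")


def _resolve_aliases(columns, aliases: dict[str, list[str]]):
    mapping = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in columns:
                mapping[name] = canonical
                break
    return mapping


def read_track_csv(path: str | Path,
                   aliases: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Track table sorted by (track_id, frame).

    The header must provide at least track id, frame and label columns
    (third-party names resolved through ``aliases``).  Duplicate
    (frame, label) pairs are an integrity error.
    """
    alias_map = dict(DEFAULT_TRACK_ALIASES)
    if aliases:
        for k, v in aliases.items():
            alias_map.setdefault(k, [])
            alias_map[k] = list(v) + alias_map[k]
    df = pd.read_csv(path)
    df = df.rename(columns=_resolve_aliases(df.columns, alias_map))
    missing = [c for c in ("track_id", "frame", "label") if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing required column(s) {missing}")
    dup = df.duplicated(subset=["frame", "label"], keep=False)
    if dup.any():
        offenders = df.loc[dup, ["frame", "label"]].drop_duplicates()
        raise IntegrityError(
            f"{path}: duplicate (frame, label) rows: "
            + ", ".join(f"({int(r.frame)}, {int(r.label)})"
                        for r in offenders.itertuples()))
    for col, default in (("y", np.nan), ("x", np.nan), ("area", 0),
                         ("parent_track", 0), ("touches_border", False)):
        if col not in df.columns:
            df[col] = default
    df = df[TRACK_COLUMNS].astype(
        {"track_id": int, "frame": int, "label": int, "area": int,
         "parent_track": int, "touches_border": bool})
    if (df["parent_track"] == df["track_id"]).any():
        raise IntegrityError(f"{path}: track is its own parent")
    return df.sort_values(["track_id", "frame"], ignore_index=True)


def write_track_csv(tracks: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = tracks[TRACK_COLUMNS].sort_values(["track_id", "frame"])
    out.to_csv(path, index=False)


def read_event_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise IntegrityError(f"{path}: missing event column(s) {missing}")
    df = df[EVENT_COLUMNS].astype(
        {"event_id": int, "kind": str, "frame": int, "parent_track": int,
         "daughter_a": int, "daughter_b": int})
    bad = df[(df.kind == "division") & ((df.daughter_a == 0) | (df.daughter_b == 0))]
    if len(bad):
        raise IntegrityError(f"{path}: division without two daughters")
    bad = df[(df.kind == "extrusion") & ((df.daughter_a != 0) | (df.daughter_b != 0))]
    if len(bad):
        raise IntegrityError(f"{path}: extrusion with daughters")
    return df


def write_event_csv(events: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events[EVENT_COLUMNS].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# edit scripts

_KNOWN_OPS = {
    "merge", "split_seeded", "draw_junction", "remove_cell", "swap_tracks",
    "set_track", "fill_hole",
}


def _check_ops(ops: list[dict], source: str) -> list[dict]:
    for i, op in enumerate(ops):
        if not isinstance(op, dict) or "op" not in op:
            raise ScriptError(i, f"{source}: record without 'op' field")
        if op["op"] not in _KNOWN_OPS:
            raise ScriptError(i, f"{source}: unknown op {op['op']!r}")
    return ops


def read_edit_script(path: str | Path) -> list[dict]:
    """Ordered, replayable list of correction operations.

    JSON (canonical: a list of objects, seed lists may be nested) or flat
    CSV (columns ``op`` + scalar args) are both accepted.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        return []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        ops = []
        for row in df.to_dict("records"):
            ops.append({k: v for k, v in row.items() if pd.notna(v)})
        for op in ops:
            for k, v in op.items():
                if isinstance(v, float) and float(v).is_integer() and k != "op":
                    op[k] = int(v)
        return _check_ops(ops, str(path))
    data = json.loads(text)
    if not isinstance(data, list):
        raise ScriptError(0, f"{path}: top level must be a JSON list")
    return _check_ops(data, str(path))


def write_edit_script(ops: list[dict], path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(ops, indent=1) + "\n")


def read_config(path: str | Path) -> dict:
    """Structured YAML run configuration (sections mirror param types)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}
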