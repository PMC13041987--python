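"""Cell-scale and track-scale feature measurement.

Feature names follow the export schema: ``area`` and ``NbNeighbor`` are
fixed verbatim, the rest are snake_case.  The shape index is
perimeter / sqrt(area) (dimensionless, >= 2*sqrt(pi) for a disk); the
perimeter estimator is the simplified crack-boundary polygon, which is
exact on axis-aligned rectangles and within a few percent on smooth
shapes.
"""

from __future__ import annotations

import math
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure as _skmeasure

from .core import LabelMovie, neighbor_graph
from .errors import GeometryError

__all__ = [
    "CELL_FEATURES",
    "cell_features",
    "track_features",
    "group_from_track_intensity",
    "temporal_table",
    "perimeter_polygonal",
]

CELL_FEATURES = (
    "area", "perimeter", "shape_index", "NbNeighbor", "orientation",
    "cytoplasmic_intensity", "junctional_intensity", "neighbors",
)
_INTENSITY_FEATURES = {"cytoplasmic_intensity", "junctional_intensity"}


def _boundary_loops(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    """Closed loops of pixel-corner points tracing the crack boundary of a
    binary mask (interior kept on the left)."""
    ys, xs = np.nonzero(mask)
    inm = set(zip(ys.tolist(), xs.tolist()))
    out: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(a, b):
        out.setdefault(a, []).append(b)

    for r, c in inm:
        if (r - 1, c) not in inm:
            add((r, c), (r, c + 1))
        if (r, c + 1) not in inm:
            add((r, c + 1), (r + 1, c + 1))
        if (r + 1, c) not in inm:
            add((r + 1, c + 1), (r + 1, c))
        if (r, c - 1) not in inm:
            add((r + 1, c), (r, c))
    loops = []
    while out:
        start = min(out)
        loop = [start]
        cur, prev = start, None
        while True:
            nxts = out[cur]
            if len(nxts) == 1:
                nxt = nxts[0]
            else:  # pinch point: prefer the sharpest right turn
                def turn(n):
                    d = (n[0] - cur[0], n[1] - cur[1])
                    return -(prev[0] * d[1] - prev[1] * d[0]) if prev else 0
                nxt = sorted(nxts, key=turn)[0]
            out[cur].remove(nxt)
            if not out[cur]:
                del out[cur]
            prev = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            loop.append(cur)
        loops.append(loop)
    return loops


def perimeter_polygonal(mask: np.ndarray, tolerance: float = 1.3) -> float:
    """Perimeter of a binary region: crack-boundary polygon simplified by
    Douglas-Peucker.  Staircases collapse to their chords, so smooth and
    polygonal shapes are both estimated within a few percent."""
    total = 0.0
    for loop in _boundary_loops(np.asarray(mask, bool)):
        if len(loop) >= 3:
            total += Polygon(loop).simplify(tolerance, preserve_topology=False).length
    return total


def cell_features(movie: LabelMovie, intensity: np.ndarray | None = None,
                  which: Iterable[str] | None = None,
                  tracks: pd.DataFrame | None = None,
                  ring_width: int = 2,
                  groups: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-(frame, label) feature table.

    ``which`` selects features from :data:`CELL_FEATURES` (default: all
    that are computable with the given inputs).  ``tracks`` maps labels to
    track ids (label == track id assumed otherwise); ``groups`` appends a
    ``group`` column keyed by track id.
    """
    if which is None:
        which = [f for f in CELL_FEATURES
                 if intensity is not None or f not in _INTENSITY_FEATURES]
    which = list(which)
    unknown = set(which) - set(CELL_FEATURES)
    if unknown:
        raise ValueError(f"unknown feature name(s): {sorted(unknown)}")
    if _INTENSITY_FEATURES & set(which) and intensity is None:
        raise ValueError("intensity movie required for intensity features")
    if intensity is not None and np.asarray(intensity).shape != movie.data.shape:
        raise GeometryError("intensity movie geometry differs from label movie")

    track_of: dict[tuple[int, int], int] = {}
    if tracks is not None:
        track_of = {(int(r.frame), int(r.label)): int(r.track_id)
                    for r in tracks.itertuples()}

    rows: list[dict] = []
    for t in range(movie.n_frames):
        frame = movie.data[t]
        graph = neighbor_graph(movie, t) if {"NbNeighbor", "neighbors"} & set(which) else None
        props = {p.label: p for p in _skmeasure.regionprops(frame)}
        for lab in sorted(props):
            p = props[lab]
            tid = track_of.get((t, lab), lab)
            row: dict = {"frame": t, "label": lab, "track_id": tid}
            mask = None
            if {"perimeter", "shape_index",
                "cytoplasmic_intensity", "junctional_intensity"} & set(which):
                mask = frame[p.slice] == lab
            if "area" in which:
                row["area"] = int(p.area)
            if "perimeter" in which or "shape_index" in which:
                per = perimeter_polygonal(mask)
                if "perimeter" in which:
                    row["perimeter"] = per
                if "shape_index" in which:
                    row["shape_index"] = per / math.sqrt(p.area)
            if "NbNeighbor" in which:
                row["NbNeighbor"] = graph.degree(lab)
            if "neighbors" in which:
                row["neighbors"] = graph.neighbors(lab)
            if "orientation" in which:
                row["orientation"] = float(p.orientation)
            if intensity is not None and {"cytoplasmic_intensity",
                                          "junctional_intensity"} & set(which):
                sub = np.asarray(intensity)[t][p.slice]
                dist = ndimage.distance_transform_edt(mask)
                if "cytoplasmic_intensity" in which:
                    core = mask & (dist > ring_width)
                    row["cytoplasmic_intensity"] = (
                        float(sub[core].mean()) if core.any()
                        else float(sub[mask].mean()))
                if "junctional_intensity" in which:
                    band = mask & (dist <= ring_width)
                    row["junctional_intensity"] = float(sub[band].mean())
            if groups is not None:
                row["group"] = groups.get(tid, "")
            rows.append(row)
    return pd.DataFrame(rows)


def track_features(tracks: pd.DataFrame,
                   frame_interval: float = 1.0) -> pd.DataFrame:
    """Duration, average speed and straightness of every track.

    duration = number of observed frames (x ``frame_interval`` for
    minutes); avg_speed = mean per-frame centroid displacement;
    straightness = net displacement / total path length (1 for a
    zero-length path).
    """
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        ys, xs = grp.y.to_numpy(float), grp.x.to_numpy(float)
        frames = grp.frame.to_numpy()
        steps = np.hypot(np.diff(ys), np.diff(xs))
        dts = np.maximum(np.diff(frames), 1)
        total = float(steps.sum())
        net = float(math.hypot(ys[-1] - ys[0], xs[-1] - xs[0]))
        rows.append({
            "track_id": int(tid),
            "duration": int(len(grp)),
            "duration_min": float(len(grp)) * frame_interval,
            "avg_speed": float((steps / dts).mean()) if len(steps) else 0.0,
            "straightness": net / total if total > 0 else 1.0,
            "parent_track": int(grp.parent_track.iloc[0]),
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "duration", "duration_min", "avg_speed", "straightness",
        "parent_track"])


def group_from_track_intensity(movie: LabelMovie, tracks: pd.DataFrame,
                               intensity: np.ndarray, threshold: float,
                               stat: str = "mean", direction: str = "above",
                               group_name: str = "group") -> dict[int, str]:
    """Classify whole tracks from their region intensity.

    A track joins ``group_name`` iff ``stat`` (mean/max/min) of its
    per-frame mean region intensities satisfies the threshold in the given
    direction (ties resolve to 'above': above means >= threshold).
    """
    if stat not in ("mean", "max", "min"):
        raise ValueError(f"unknown stat {stat!r}")
    if direction not in ("above", "below"):
        raise ValueError(f"unknown direction {direction!r}")
    inten = np.asarray(intensity)
    if inten.shape != movie.data.shape:
        raise GeometryError("intensity movie geometry differs from label movie")
    out: dict[int, str] = {}
    for tid, grp in tracks.groupby("track_id"):
        if grp.empty:
            continue
        means = []
        for r in grp.itertuples():
            mask = movie.data[int(r.frame)] == int(r.label)
            means.append(float(inten[int(r.frame)][mask].mean()))
        agg = {"mean": np.mean, "max": np.max, "min": np.min}[stat](means)
        member = agg >= threshold if direction == "above" else agg < threshold
        out[int(tid)] = group_name if member else ""
    return out


def temporal_table(rows: pd.DataFrame, feature: str,
                   by_group: bool = False) -> pd.DataFrame:
    """Per-frame (and per-group) mean with 0.95 normal-approximation CI
    half-width (1.96 * sd / sqrt(n); missing when n < 2)."""
    if feature not in rows.columns:
        raise ValueError(f"feature {feature!r} not in table")
    keys = ["frame", "group"] if by_group else ["frame"]
    if by_group and "group" not in rows.columns:
        raise ValueError("by_group requires a 'group' column")
    recs = []
    for key, grp in rows.groupby(keys):
        vals = grp[feature].dropna().to_numpy(float)
        n = len(vals)
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["n"] = n
        rec["mean"] = float(vals.mean()) if n else math.nan
        rec["ci95"] = (1.96 * float(vals.std(ddof=1)) / math.sqrt(n)
                       if n >= 2 else math.nan)
        recs.append(rec)
    return pd.DataFrame(recs).sort_values(keys, ignore_index=True)
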