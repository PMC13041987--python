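"""Division/extrusion detection, probability-map filtering, fate groups.

A division is recorded when one track disappears and two tracks appear very
nearby at the next frame; the event sits at the midpoint of the two
daughters at their first frame.  An extrusion is a track that disappears
before the movie ends, away from the border, without a division and with a
small final apical area; the event sits at the cell's last visible
centroid.  Detected events can be cross-filtered against an external
event-probability movie, keeping only detections with high probability in
a spatiotemporal window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, IntegrityError
from .io import EVENT_COLUMNS
from .tracking import division_candidates

__all__ = [
    "EventParams",
    "detect_divisions",
    "detect_extrusions",
    "filter_events_by_probability",
    "fate_groups",
    "relative_area_to_event",
]


@dataclass(frozen=True)
class EventParams:
    """``div_radius=None`` auto-scales to 2x the median cell diameter of
    the frame; ``extrusion_area_max`` is a fraction of the frame-median
    area unless ``extrusion_area_is_fraction`` is False (then pixels)."""

    div_radius: float | None = None
    extrusion_area_max: float = 0.25
    extrusion_area_is_fraction: bool = True
    prob_threshold: float = 0.5
    prob_window_px: int = 10
    prob_window_frames: int = 2

    def __post_init__(self):
        if not 0 <= self.prob_threshold <= 1:
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.extrusion_area_max <= 0:
            raise ValueError("extrusion_area_max must be > 0")


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(columns=EVENT_COLUMNS).astype(
        {"event_id": int, "kind": str, "frame": int, "y": float, "x": float,
         "parent_track": int, "daughter_a": int, "daughter_b": int})


def detect_divisions(tracks: pd.DataFrame,
                     params: EventParams | None = None) -> pd.DataFrame:
    """One track ends, two tracks start nearby at the next frame."""
    params = params or EventParams()
    rows = []
    for k, cand in enumerate(division_candidates(tracks, params.div_radius)):
        da, db = cand["daughters"]
        rows.append({"event_id": k + 1, "kind": "division",
                     "frame": cand["frame"], "y": cand["y"], "x": cand["x"],
                     "parent_track": cand["parent"],
                     "daughter_a": da, "daughter_b": db})
    return pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else _empty_events()


def detect_extrusions(tracks: pd.DataFrame, divisions: pd.DataFrame,
                      params: EventParams | None = None) -> pd.DataFrame:
    """Track ends early, interior, no division, small final area."""
    params = params or EventParams()
    if tracks.empty:
        return _empty_events()
    t_max = int(tracks["frame"].max())
    med_area = tracks.groupby("frame")["area"].median()
    div_parents = set(divisions["parent_track"].astype(int)) if len(divisions) else set()
    next_id = (int(divisions["event_id"].max()) + 1) if len(divisions) else 1
    rows = []
    for tid, grp in tracks.groupby("track_id"):
        last = grp.loc[grp["frame"].idxmax()]
        t_end = int(last.frame)
        if t_end >= t_max or int(tid) in div_parents or bool(last.touches_border):
            continue
        amax = params.extrusion_area_max
        if params.extrusion_area_is_fraction:
            amax = amax * float(med_area[t_end])
        if float(last.area) <= amax:
            rows.append({"event_id": next_id, "kind": "extrusion",
                         "frame": t_end, "y": float(last.y), "x": float(last.x),
                         "parent_track": int(tid),
                         "daughter_a": 0, "daughter_b": 0})
            next_id += 1
    return pd.DataFrame(rows, columns=EVENT_COLUMNS) if rows else _empty_events()


def filter_events_by_probability(events: pd.DataFrame, prob_movie: np.ndarray,
                                 params: EventParams | None = None
                                 ) -> pd.DataFrame:
    """Keep an event iff the probability movie reaches the threshold in a
    window of +/- ``prob_window_px`` pixels and ``prob_window_frames``
    frames around it.  Order preserved; monotone in the threshold."""
    params = params or EventParams()
    prob = np.asarray(prob_movie)
    if prob.ndim != 3:
        raise GeometryError("probability movie must be T x Y x X")
    T, H, W = prob.shape
    keep = []
    for row in events.itertuples():
        if not 0 <= int(row.frame) < T:
            raise GeometryError(
                f"event frame {row.frame} outside probability movie (T={T})")
        t0 = max(0, int(row.frame) - params.prob_window_frames)
        t1 = min(T, int(row.frame) + params.prob_window_frames + 1)
        y0 = max(0, int(round(row.y)) - params.prob_window_px)
        y1 = min(H, int(round(row.y)) + params.prob_window_px + 1)
        x0 = max(0, int(round(row.x)) - params.prob_window_px)
        x1 = min(W, int(round(row.x)) + params.prob_window_px + 1)
        keep.append(float(prob[t0:t1, y0:y1, x0:x1].max()) >= params.prob_threshold)
    return events[np.asarray(keep, dtype=bool)].reset_index(drop=True)


def fate_groups(tracks: pd.DataFrame, events: pd.DataFrame) -> dict[int, str]:
    """Map track_id -> 'Dividing' | 'Extruding' | '' (terminal-track
    semantics: only the division parent / extruding track is marked)."""
    groups = {int(t): "" for t in tracks["track_id"].unique()}
    for row in events.itertuples():
        tid = int(row.parent_track)
        new = "Dividing" if row.kind == "division" else "Extruding"
        if tid in groups and groups[tid] and groups[tid] != new:
            raise IntegrityError(
                f"track {tid} cannot both divide and extrude")
        if tid in groups:
            groups[tid] = new
    return groups


def relative_area_to_event(events: pd.DataFrame, features: pd.DataFrame
                           ) -> dict[int, pd.DataFrame]:
    """Per-event series of A_cell(t) / mean(A_neighbors(t)).

    ``features`` needs columns (frame, label, track_id, area, neighbors)
    where ``neighbors`` is a list of neighboring labels in that frame (see
    :func:`epimend.measures.cell_features` with the neighbors feature).
    The series runs from the terminal track's start to the event and is
    aligned so the event frame is 0 (negative before).  Frames where the
    cell has no neighbors yield a missing ratio.
    """
    area_of = {(int(r.frame), int(r.label)): float(r.area)
               for r in features.itertuples()}
    out: dict[int, pd.DataFrame] = {}
    for ev in events.itertuples():
        tid = int(ev.parent_track)
        cell = features[features.track_id == tid].sort_values("frame")
        recs = []
        for r in cell.itertuples():
            if int(r.frame) >= int(ev.frame) and ev.kind == "division":
                continue
            if int(r.frame) > int(ev.frame):
                continue
            neigh = [area_of.get((int(r.frame), int(n))) for n in r.neighbors]
            neigh = [a for a in neigh if a is not None]
            ratio = float(r.area) / (sum(neigh) / len(neigh)) if neigh else math.nan
            recs.append({"t_rel": int(r.frame) - int(ev.frame),
                         "frame": int(r.frame), "ratio": ratio})
        out[int(ev.event_id)] = pd.DataFrame(recs, columns=["t_rel", "frame", "ratio"])
    return out
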