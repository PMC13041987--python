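"""Correction operators with automatic track relinking.

All operators work on curated movies in which labels are track ids (see
:func:`epimend.tracking.relabel_movie_by_tracks`); they mutate the movie
in place, invoke :func:`epimend.tracking.relink_after_edit` on the touched
labels, and return the updated ``(movie, tracks)``.  Fresh labels are
drawn from a monotone counter (max over all frames + 1) and never reused,
so every cell keeps a unique id.  Replay of a recorded script is the
batch, headless equivalent of the interactive one-click corrections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import line as _draw_line
from skimage.segmentation import watershed

from .core import LabelMovie, detect_representation, neighbor_graph
from .errors import EditError, ScriptError
from .tracking import TrackingParams, relink_after_edit, tracks_from_labels

__all__ = [
    "merge", "split_seeded", "draw_junction", "remove_cell", "swap_tracks",
    "set_track", "fill_hole", "apply_script",
]


def _fresh_label(movie: LabelMovie, tracks: pd.DataFrame | None) -> int:
    top = int(movie.data.max())
    if tracks is not None and len(tracks):
        top = max(top, int(tracks["track_id"].max()))
    return top + 1


def _ensure_tracks(movie, tracks):
    return tracks if tracks is not None else tracks_from_labels(movie)


def _require_label(movie: LabelMovie, frame: int, label: int) -> np.ndarray:
    mask = movie.frame(frame) == label
    if not mask.any():
        raise EditError(f"label {label} absent at frame {frame}")
    return mask


def merge(movie: LabelMovie, tracks: pd.DataFrame | None, frame: int,
          label_a: int, label_b: int,
          params: TrackingParams | None = None):
    """Merge two adjacent cells into one; the union keeps the lower id and
    absorbs any junction-gap pixels strictly between the two regions."""
    if label_a == label_b:
        raise EditError("merge needs two distinct labels")
    tracks = _ensure_tracks(movie, tracks)
    mask_a = _require_label(movie, frame, label_a)
    mask_b = _require_label(movie, frame, label_b)
    graph = neighbor_graph(movie, frame)
    if not graph.has_edge(label_a, label_b):
        raise EditError(
            f"labels {label_a} and {label_b} are not adjacent at frame {frame}; "
            "refusing to merge distant cells")
    img = movie.data[frame]
    kept, gone = min(label_a, label_b), max(label_a, label_b)
    between = ((img == 0)
               & ndimage.binary_dilation(mask_a, structure=np.ones((3, 3)))
               & ndimage.binary_dilation(mask_b, structure=np.ones((3, 3))))
    img[mask_a | mask_b | between] = kept
    return relink_after_edit(movie, tracks, frame, {kept}, params)


def split_seeded(movie: LabelMovie, tracks: pd.DataFrame | None, frame: int,
                 label: int, seeds: list[tuple[int, int]] | None = None,
                 seed_groups: list[list[tuple[int, int]]] | None = None,
                 intensity_frame: np.ndarray | None = None,
                 params: TrackingParams | None = None):
    """Split one cell by marker-based watershed restricted to its region.

    Markers are individual ``seeds`` (one marker each) or ``seed_groups``
    (each group one marker; groups may cover whole subregions, which makes
    the split reproduce the group partition exactly).  The relief is the
    intensity image if given, else the inverted distance transform of the
    region.  The part holding the first seed keeps ``label``; other parts
    get fresh ids.
    """
    tracks = _ensure_tracks(movie, tracks)
    mask = _require_label(movie, frame, label)
    if seed_groups is None:
        if seeds is None or len(seeds) < 2:
            raise EditError("split_seeded needs >= 2 seeds")
        seed_groups = [[tuple(s)] for s in seeds]
    if len(seed_groups) < 2:
        raise EditError("split_seeded needs >= 2 seed groups")
    markers = np.zeros_like(movie.data[frame], dtype=np.int32)
    for gi, group in enumerate(seed_groups, start=1):
        for (sy, sx) in group:
            sy, sx = int(sy), int(sx)
            if not (0 <= sy < mask.shape[0] and 0 <= sx < mask.shape[1]) \
                    or not mask[sy, sx]:
                raise EditError(f"seed ({sy}, {sx}) outside region of label {label}")
            markers[sy, sx] = gi
    if intensity_frame is not None:
        relief = np.asarray(intensity_frame, dtype=float)
        if relief.shape != mask.shape:
            raise EditError("intensity frame geometry differs from movie frame")
    else:
        padded = np.pad(mask, 1)
        relief = -ndimage.distance_transform_edt(padded)[1:-1, 1:-1]
    parts = watershed(relief, markers=markers, mask=mask, connectivity=1)
    img = movie.data[frame]
    new_labels = [label]
    for gi in range(2, len(seed_groups) + 1):
        fresh = _fresh_label(movie, tracks)
        img[parts == gi] = fresh
        new_labels.append(fresh)
    return relink_after_edit(movie, tracks, frame, set(new_labels), params)


def draw_junction(movie: LabelMovie, tracks: pd.DataFrame | None, frame: int,
                  polyline: list[tuple[int, int]],
                  params: TrackingParams | None = None):
    """Split a cell along a drawn junction line.

    The polyline is rasterized segment by segment (Bresenham); its interior
    must stay within a single cell, and removing it must leave exactly two
    components.  In the junction-gap representation the path becomes
    background; in the dense representation path pixels join the nearest
    part.
    """
    tracks = _ensure_tracks(movie, tracks)
    if len(polyline) < 2:
        raise EditError("polyline needs >= 2 points")
    img = movie.data[frame]
    path_y, path_x = [], []
    pts = [(int(y), int(x)) for y, x in polyline]
    for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
        ry, rx = _draw_line(y0, x0, y1, x1)
        path_y.extend(ry.tolist())
        path_x.extend(rx.tolist())
    path = np.zeros_like(img, dtype=bool)
    path[path_y, path_x] = True
    interior = path.copy()
    interior[pts[0]] = interior[pts[-1]] = False
    labs = np.unique(img[interior])
    labs = labs[labs > 0]
    if len(labs) != 1:
        raise EditError(
            f"junction path must stay within one cell, crosses labels {labs.tolist()}")
    label = int(labs[0])
    mask = img == label
    cut = mask & ~path
    comp, n_comp = ndimage.label(cut, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n_comp != 2:
        raise EditError(
            f"junction path does not separate cell {label} into two parts "
            f"(got {n_comp})")
    fresh = _fresh_label(movie, tracks)
    img[comp == 2] = fresh
    inpath = mask & path
    if detect_representation(movie) == "junction-gap":
        img[inpath] = 0
    else:
        # attach each path pixel to the nearest of the two parts
        d1 = ndimage.distance_transform_edt(comp != 1)
        d2 = ndimage.distance_transform_edt(comp != 2)
        img[inpath & (d1 <= d2)] = label
        img[inpath & (d1 > d2)] = fresh
    return relink_after_edit(movie, tracks, frame, {label, fresh}, params)


def remove_cell(movie: LabelMovie, tracks: pd.DataFrame | None,
                frame_from: int, track_id: int, repair: bool = False,
                params: TrackingParams | None = None):
    """Truncate a track: its pixels become background from ``frame_from``
    on (or are absorbed by the longest-boundary neighbor with
    ``repair=True``)."""
    tracks = _ensure_tracks(movie, tracks)
    sel = tracks[(tracks.track_id == track_id) & (tracks.frame == frame_from)]
    if sel.empty:
        raise EditError(f"track {track_id} does not exist at frame {frame_from}")
    parents = {int(r.track_id): int(r.parent_track)
               for r in tracks.itertuples() if r.parent_track}
    for t in range(frame_from, movie.n_frames):
        mask = movie.data[t] == track_id
        if not mask.any():
            continue
        if repair:
            graph = neighbor_graph(movie, t)
            neighbors = graph.neighbors(track_id)
            if neighbors:
                best = max(neighbors,
                           key=lambda n: (graph.boundary_length(track_id, n), -n))
                movie.data[t][mask] = best
                continue
        movie.data[t][mask] = 0
    parents.pop(int(track_id), None)
    return movie, tracks_from_labels(movie, parents)


def swap_tracks(movie: LabelMovie, tracks: pd.DataFrame | None,
                frame_from: int, id_a: int, id_b: int,
                params: TrackingParams | None = None):
    """Exchange the identities of two tracks from ``frame_from`` to each
    track's end (involution: applying it twice is the identity)."""
    tracks = _ensure_tracks(movie, tracks)
    if id_a == id_b:
        return movie, tracks
    for tid in (id_a, id_b):
        if tracks[(tracks.track_id == tid) & (tracks.frame >= frame_from)].empty:
            raise EditError(f"track {tid} does not exist at/after frame {frame_from}")
    for t in range(frame_from, movie.n_frames):
        ma = movie.data[t] == id_a
        mb = movie.data[t] == id_b
        movie.data[t][ma] = id_b
        movie.data[t][mb] = id_a
    parents = {}
    swap_map = {id_a: id_b, id_b: id_a}
    for r in tracks.itertuples():
        if r.parent_track:
            tid = int(r.track_id)
            parents[swap_map.get(tid, tid)] = swap_map.get(
                int(r.parent_track), int(r.parent_track))
    return movie, tracks_from_labels(movie, parents)


def set_track(movie: LabelMovie, tracks: pd.DataFrame | None,
              frame_from: int, track_id: int, new_id: int,
              params: TrackingParams | None = None):
    """Re-assign a track id from ``frame_from`` onward."""
    tracks = _ensure_tracks(movie, tracks)
    if track_id == new_id:
        return movie, tracks
    sel = tracks[(tracks.track_id == track_id) & (tracks.frame >= frame_from)]
    if sel.empty:
        raise EditError(f"track {track_id} does not exist at/after frame {frame_from}")
    later = movie.data[frame_from:]
    if (later == new_id).any():
        raise EditError(f"track id {new_id} already in use after frame {frame_from}")
    later[later == track_id] = new_id
    parents = {int(r.track_id): int(r.parent_track)
               for r in tracks.itertuples() if r.parent_track}
    if track_id in parents:
        parents[new_id] = parents.pop(track_id)
    return movie, tracks_from_labels(movie, parents)


def fill_hole(movie: LabelMovie, tracks: pd.DataFrame | None, frame: int,
              y: int, x: int, params: TrackingParams | None = None):
    """Fill the 4-connected background component containing (y, x) with a
    cell, restoring a one-frame dropout; relinking decides the track id
    from the overlap with the adjacent frames."""
    tracks = _ensure_tracks(movie, tracks)
    img = movie.data[frame]
    y, x = int(y), int(x)
    if img[y, x] != 0:
        raise EditError(f"({y}, {x}) at frame {frame} is not background")
    bg, _ = ndimage.label(img == 0, structure=np.array(
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    hole = bg == bg[y, x]
    fresh = _fresh_label(movie, tracks)
    img[hole] = fresh
    return relink_after_edit(movie, tracks, frame, {fresh}, params)


_OP_TABLE = {
    "merge": lambda mv, tr, op, pr: merge(
        mv, tr, op["frame"], op["label_a"], op["label_b"], pr),
    "split_seeded": lambda mv, tr, op, pr: split_seeded(
        mv, tr, op["frame"], op["label"], seeds=op.get("seeds"),
        seed_groups=op.get("seed_groups"), params=pr),
    "draw_junction": lambda mv, tr, op, pr: draw_junction(
        mv, tr, op["frame"], op["polyline"], pr),
    "remove_cell": lambda mv, tr, op, pr: remove_cell(
        mv, tr, op["frame_from"], op["track_id"],
        repair=op.get("repair", False), params=pr),
    "swap_tracks": lambda mv, tr, op, pr: swap_tracks(
        mv, tr, op["frame_from"], op["id_a"], op["id_b"], pr),
    "set_track": lambda mv, tr, op, pr: set_track(
        mv, tr, op["frame_from"], op["track_id"], op["new_id"], pr),
    "fill_hole": lambda mv, tr, op, pr: fill_hole(
        mv, tr, op["frame"], op["y"], op["x"], pr),
}


def apply_script(movie: LabelMovie, tracks: pd.DataFrame | None,
                 script: list[dict],
                 params: TrackingParams | None = None):
    """Replay an edit script in order.

    Returns ``(movie, tracks, log)``; a failing op k raises
    :class:`ScriptError` with ops 0..k-1 already applied.
    """
    tracks = _ensure_tracks(movie, tracks)
    log: list[dict] = []
    for k, op in enumerate(script):
        name = op.get("op")
        if name not in _OP_TABLE:
            raise ScriptError(k, f"unknown op {name!r}")
        try:
            movie, tracks = _OP_TABLE[name](movie, tracks, op, params)
        except ScriptError:
            raise
        except Exception as exc:
            raise ScriptError(k, f"{name}: {exc}") from exc
        log.append({"position": k, "op": name, "status": "ok"})
    return movie, tracks, log
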