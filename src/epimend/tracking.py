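"""Track construction by frame-to-frame linear assignment.

Cells in consecutive frames are matched by minimizing a cost that combines
squared centroid distance with a scale-free relative-area penalty::

    cost(i, j) = d(c_i, c_j)^2 * (1 + w_A * |A_i - A_j| / max(A_i, A_j))

Links beyond ``max_link_distance`` or beyond the relative area-change gate
are forbidden.  Unmatched cells open or close tracks; gap closing joins a
track end to a later start; division hypotheses are evaluated post hoc on
unmatched starts (one end, two nearby starts -> parent/daughter edges).
After a local edit, ``relink_after_edit`` re-attaches the touched cells to
the surrounding tracks by majority pixel overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .core import LabelMovie, RegionRecord, region_table
from .errors import EditError, IntegrityError
from .io import TRACK_COLUMNS

__all__ = [
    "TrackingParams",
    "Assignment",
    "link_cost",
    "link_frames",
    "build_tracks",
    "relink_after_edit",
    "tracks_from_labels",
    "relabel_movie_by_tracks",
    "division_candidates",
]

_BIG = 1e12  # forbidden-link sentinel; finite so the LAP stays feasible
_TIE_EPS = 1e-9  # deterministic preference for low-index pairs among ties


@dataclass(frozen=True)
class TrackingParams:
    """Knobs of the linker, all exposed on the CLI.

    ``division_search_radius=None`` auto-scales to 2x the median cell
    diameter of the frame under consideration.  ``max_area_change`` is the
    hard similar-area gate (relative difference) that keeps a parent from
    being linked straight onto one of its daughters.
    """

    max_link_distance: float = 15.0
    area_weight: float = 1.0
    max_gap_frames: int = 0
    division_search_radius: float | None = None
    use_overlap: bool = True
    max_area_change: float = 0.42
    area_change_floor: float = 80.0
    min_link_overlap: float = 0.2
    overlap_min: float = 0.5

    def __post_init__(self):
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be > 0")
        if self.division_search_radius is not None and self.division_search_radius <= 0:
            raise ValueError("division_search_radius must be > 0")
        if self.area_weight < 0 or self.max_gap_frames < 0:
            raise ValueError("area_weight and max_gap_frames must be >= 0")


@dataclass(frozen=True)
class Assignment:
    """Result of matching two frames: label pairs plus unmatched labels."""

    pairs: tuple[tuple[int, int], ...]
    unmatched_a: tuple[int, ...]
    unmatched_b: tuple[int, ...]
    total_cost: float


def link_cost(a: RegionRecord, b: RegionRecord, params: TrackingParams,
              distance_allowance: float | None = None) -> float:
    """Cost of linking two regions; ``inf`` when the link is forbidden."""
    allow = params.max_link_distance if distance_allowance is None else distance_allowance
    d2 = (a.centroid[0] - b.centroid[0]) ** 2 + (a.centroid[1] - b.centroid[1]) ** 2
    if d2 > allow * allow:
        return math.inf
    rel = abs(a.area - b.area) / max(a.area, b.area)
    if rel > params.max_area_change \
            and abs(a.area - b.area) > params.area_change_floor:
        return math.inf
    return d2 * (1.0 + params.area_weight * rel)


def link_frames(regions_a: list[RegionRecord], regions_b: list[RegionRecord],
                params: TrackingParams,
                overlaps: dict[tuple[int, int], int] | None = None
                ) -> Assignment:
    """Optimal one-to-one matching between two consecutive frames.

    Solved as a rectangular LAP with a per-region no-link alternative
    priced at ``max_link_distance**2``; minimizes
    ``sum(cost) + price * n_unmatched``.  Deterministic: equal-cost optima
    resolve toward low (sorted-by-label) index pairs.

    ``overlaps`` maps (label_a, label_b) to shared pixel counts; when
    given (and ``use_overlap`` is on) links whose overlap covers less than
    ``min_link_overlap`` of the smaller region are forbidden, which stops
    a disappearing cell from being relinked onto a mere neighbor.
    """
    ra = sorted(regions_a, key=lambda r: r.label)
    rb = sorted(regions_b, key=lambda r: r.label)
    n, m = len(ra), len(rb)
    price = params.max_link_distance ** 2
    if n == 0 or m == 0:
        return Assignment((), tuple(r.label for r in ra),
                          tuple(r.label for r in rb),
                          price * (n + m))
    full = np.full((n + m, m + n), _BIG)
    for i, a in enumerate(ra):
        for j, b in enumerate(rb):
            c = link_cost(a, b, params)
            if overlaps is not None and params.use_overlap \
                    and math.isfinite(c):
                frac = overlaps.get((a.label, b.label), 0) / min(a.area, b.area)
                if frac < params.min_link_overlap:
                    c = math.inf
            if math.isfinite(c):
                full[i, j] = c + _TIE_EPS * (i * m + j)
    full[np.arange(n), m + np.arange(n)] = price  # a-side no-link
    full[n + np.arange(m), np.arange(m)] = price  # b-side no-link
    full[n:, m:] = 0.0
    rows, cols = linear_sum_assignment(full)
    by_label_a = {r.label: r for r in ra}
    by_label_b = {r.label: r for r in rb}
    pairs, ua, ub = [], set(range(n)), set(range(m))
    for i, j in zip(rows, cols):
        if i < n and j < m and full[i, j] < _BIG:
            pairs.append((ra[i].label, rb[j].label))
            ua.discard(i)
            ub.discard(j)
    total = sum(link_cost(by_label_a[a], by_label_b[b], params)
                for a, b in pairs) + price * (len(ua) + len(ub))
    return Assignment(tuple(pairs),
                      tuple(ra[i].label for i in sorted(ua)),
                      tuple(rb[j].label for j in sorted(ub)),
                      float(total))


def _frame_overlaps(fa: np.ndarray, fb: np.ndarray) -> dict[tuple[int, int], int]:
    """Pixel-overlap counts between the labels of two aligned frames."""
    m = (fa > 0) & (fb > 0)
    if not m.any():
        return {}
    k = int(fb.max()) + 1
    joint = fa[m].astype(np.int64) * k + fb[m].astype(np.int64)
    uniq, cnt = np.unique(joint, return_counts=True)
    return {(int(u // k), int(u % k)): int(c) for u, c in zip(uniq, cnt)}


def _auto_div_radius(areas: np.ndarray) -> float:
    """2 x median cell diameter (area-equivalent circle)."""
    med = float(np.median(areas))
    return 4.0 * math.sqrt(med / math.pi)


def division_candidates(tracks: pd.DataFrame,
                        div_radius: float | None = None
                        ) -> list[dict]:
    """Shared division rule: a track ending at t with >= 2 tracks starting
    at t+1 whose start centroids lie within the search radius of its end
    centroid yields a division; the two nearest starters become daughters
    and each starter is consumed by at most one division.

    Returns records with parent, daughters, event frame (first frame the
    daughters exist) and event position (midpoint of the daughters then).
    """
    if tracks.empty:
        return []
    t_max = int(tracks["frame"].max())
    grouped = tracks.groupby("track_id")
    first_frame = grouped["frame"].min()
    last_frame = grouped["frame"].max()
    ends = tracks.merge(
        last_frame.rename("last"), left_on="track_id", right_index=True)
    ends = ends[(ends.frame == ends["last"]) & (ends.frame < t_max)]
    starts = tracks.merge(
        first_frame.rename("first"), left_on="track_id", right_index=True)
    starts = starts[(starts.frame == starts["first"]) & (starts.frame > 0)]
    starts_by_frame = {f: g for f, g in starts.groupby("frame")}
    med_area_by_frame = tracks.groupby("frame")["area"].median()

    consumed: set[int] = set()
    out = []
    for end in ends.sort_values(["frame", "track_id"]).itertuples():
        cand = starts_by_frame.get(end.frame + 1)
        if cand is None:
            continue
        if div_radius is None:
            med = float(med_area_by_frame.get(end.frame, np.nan))
            radius = 4.0 * math.sqrt(med / math.pi)
        else:
            radius = div_radius
        free = cand[~cand.track_id.isin(consumed) & (cand.track_id != end.track_id)]
        if len(free) < 2:
            continue
        d = np.hypot(free.y.to_numpy() - end.y, free.x.to_numpy() - end.x)
        order = np.lexsort((free.track_id.to_numpy(), d))
        near = [k for k in order if d[k] <= radius]
        if len(near) < 2:
            continue
        i1, i2 = near[0], near[1]
        d1, d2 = int(free.iloc[i1].track_id), int(free.iloc[i2].track_id)
        da, db = sorted((d1, d2))
        consumed.update((da, db))
        y = (free.iloc[i1].y + free.iloc[i2].y) / 2.0
        x = (free.iloc[i1].x + free.iloc[i2].x) / 2.0
        out.append({"parent": int(end.track_id), "frame": int(end.frame) + 1,
                    "daughters": (da, db), "y": float(y), "x": float(x)})
    return out


def _records_to_rows(records: list[RegionRecord], track_ids: dict[int, int],
                     parents: dict[int, int]) -> list[dict]:
    rows = []
    for r in records:
        tid = track_ids[r.label]
        rows.append({
            "track_id": tid, "frame": r.frame, "label": r.label,
            "y": r.centroid[0], "x": r.centroid[1], "area": r.area,
            "parent_track": parents.get(tid, 0),
            "touches_border": r.touches_border,
        })
    return rows


def build_tracks(movie: LabelMovie, params: TrackingParams | None = None
                 ) -> pd.DataFrame:
    """Track every (frame, label) observation of a movie.

    Every observation lands in exactly one track; unmatched starts open new
    track ids; gap closing joins compatible end/start pairs separated by up
    to ``max_gap_frames`` missing frames; division hypotheses set
    ``parent_track`` on daughter tracks.
    """
    params = params or TrackingParams()
    regions = [region_table(movie, t) for t in range(movie.n_frames)]
    next_id = 1
    ids_per_frame: list[dict[int, int]] = []
    for t, regs in enumerate(regions):
        ids: dict[int, int] = {}
        if t == 0:
            for r in sorted(regs, key=lambda r: r.label):
                ids[r.label] = next_id
                next_id += 1
        else:
            overlaps = (_frame_overlaps(movie.data[t - 1], movie.data[t])
                        if params.use_overlap else None)
            assn = link_frames(regions[t - 1], regs, params, overlaps)
            prev_ids = ids_per_frame[t - 1]
            for a, b in assn.pairs:
                ids[b] = prev_ids[a]
            for b in assn.unmatched_b:
                ids[b] = next_id
                next_id += 1
        ids_per_frame.append(ids)

    rows: list[dict] = []
    for t, regs in enumerate(regions):
        rows.extend(_records_to_rows(regs, ids_per_frame[t], {}))
    tracks = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    if tracks.empty:
        return tracks

    if params.max_gap_frames > 0:
        tracks = _close_gaps(tracks, regions, ids_per_frame, params)

    for cand in division_candidates(tracks, params.division_search_radius):
        for d in cand["daughters"]:
            tracks.loc[tracks.track_id == d, "parent_track"] = cand["parent"]
    return tracks.sort_values(["track_id", "frame"], ignore_index=True)


def _close_gaps(tracks: pd.DataFrame, regions, ids_per_frame, params):
    """Greedy cost-ascending gap closing over (track end, track start)
    pairs with 1..max_gap_frames missing frames; distance allowance scales
    with (gap + 1)."""
    reg_by = {(r.frame, r.label): r for regs in regions for r in regs}
    t_max = int(tracks["frame"].max())
    g = tracks.groupby("track_id")["frame"]
    last, first = g.max(), g.min()
    ends = [(tid, int(f)) for tid, f in last.items() if f < t_max]
    starts = [(tid, int(f)) for tid, f in first.items() if f > 0]
    lab = tracks.set_index(["track_id", "frame"])["label"]
    cands = []
    for e_tid, e_f in ends:
        for s_tid, s_f in starts:
            gap = s_f - e_f - 1
            if not 1 <= gap <= params.max_gap_frames or e_tid == s_tid:
                continue
            ra = reg_by[(e_f, int(lab[(e_tid, e_f)]))]
            rb = reg_by[(s_f, int(lab[(s_tid, s_f)]))]
            c = link_cost(ra, rb, params,
                          distance_allowance=params.max_link_distance * (gap + 1))
            if math.isfinite(c):
                cands.append((c, e_tid, s_tid))
    used_e: set[int] = set()
    used_s: set[int] = set()
    renames: dict[int, int] = {}
    for c, e_tid, s_tid in sorted(cands):
        if e_tid in used_e or s_tid in used_s:
            continue
        used_e.add(e_tid)
        used_s.add(s_tid)
        renames[s_tid] = e_tid
    # follow chains (end A <- start B, end B <- start C)
    def resolve(tid):
        while tid in renames:
            tid = renames[tid]
        return tid
    if renames:
        tracks = tracks.copy()
        tracks["track_id"] = tracks["track_id"].map(resolve)
        tracks["parent_track"] = tracks["parent_track"].map(
            lambda p: resolve(p) if p else 0)
    return tracks


def tracks_from_labels(movie: LabelMovie,
                       parents: dict[int, int] | None = None) -> pd.DataFrame:
    """Track table of a curated movie whose labels already are track ids
    (one label = one temporal identity)."""
    parents = parents or {}
    rows: list[dict] = []
    for t in range(movie.n_frames):
        regs = region_table(movie, t)
        rows.extend(_records_to_rows(regs, {r.label: r.label for r in regs},
                                     parents))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    return df.sort_values(["track_id", "frame"], ignore_index=True)


def relabel_movie_by_tracks(movie: LabelMovie, tracks: pd.DataFrame
                            ) -> tuple[LabelMovie, pd.DataFrame]:
    """Rewrite movie labels as track ids so label == temporal identity."""
    out = movie.copy()
    for t, grp in tracks.groupby("frame"):
        frame = movie.data[int(t)]
        mapping = np.zeros(int(frame.max()) + 1, dtype=out.data.dtype)
        for row in grp.itertuples():
            mapping[int(row.label)] = int(row.track_id)
        out.data[int(t)] = mapping[frame]
    new = tracks.copy()
    new["label"] = new["track_id"]
    return out, new.sort_values(["track_id", "frame"], ignore_index=True)


def _overlap_best(mask: np.ndarray, other_frame: np.ndarray,
                  min_frac: float) -> int | None:
    """Label of `other_frame` with maximal pixel overlap with ``mask``,
    provided the overlap covers >= min_frac of the smaller region."""
    vals = other_frame[mask]
    vals = vals[vals > 0]
    if vals.size == 0:
        return None
    counts = np.bincount(vals)
    best = int(counts.argmax())
    inter = int(counts[best])
    other_area = int((other_frame == best).sum())
    frac = inter / min(int(mask.sum()), other_area)
    return best if frac >= min_frac else None


def relink_after_edit(movie: LabelMovie, tracks: pd.DataFrame, frame: int,
                      touched_labels: set[int],
                      params: TrackingParams | None = None
                      ) -> tuple[LabelMovie, pd.DataFrame]:
    """Re-attach edited cells to the surrounding tracks.

    Requires the curated convention label == track_id (see
    :func:`relabel_movie_by_tracks`).  For each touched label the frame-1
    and frame+1 regions with maximal pixel overlap are found; with overlap
    >= ``overlap_min`` (fraction of the smaller region) the label inherits
    the predecessor's id and the successor chain is re-labeled to match.
    A cell with no usable neighbor keeps (opens) its own track id.  Only
    tracks overlapping the edited cells at frame +/- 1 are modified.
    """
    params = params or TrackingParams()
    if not tracks.empty and (tracks["label"] != tracks["track_id"]).any():
        raise IntegrityError(
            "relink_after_edit requires label == track_id "
            "(use relabel_movie_by_tracks first)")
    data = movie.data
    present = set(np.unique(data[frame]).tolist())
    for lab in touched_labels:
        if lab not in present:
            raise EditError(f"touched label {lab} absent at frame {frame}")
    parents = {int(r.track_id): int(r.parent_track)
               for r in tracks.itertuples() if r.parent_track}
    for lab in sorted(touched_labels):
        mask = data[frame] == lab
        if not mask.any():  # renamed by an earlier touched label
            continue
        pred = None
        if frame > 0:
            pred = _overlap_best(mask, data[frame - 1], params.overlap_min)
        succ = None
        if frame < movie.n_frames - 1:
            succ = _overlap_best(mask, data[frame + 1], params.overlap_min)
        target = pred if pred is not None else succ
        if target is None:
            continue  # fresh track of length 1 (keeps its own id)
        if target != lab:
            if (data[frame] == target).any():
                continue  # target still alive in this frame: ambiguous, keep
            data[frame][mask] = target
            if lab in parents:
                parents[target] = parents.pop(lab)
        if succ is not None and succ != target:
            # re-label the successor chain unless it predates the edit
            if (data[frame] == succ).any():
                continue
            later = data[frame + 1:]
            if ((later == target).any()):
                continue  # would collide with target's own continuation
            later[later == succ] = target
            if succ in parents:
                parents[target] = parents.pop(succ)
    return movie, tracks_from_labels(movie, parents)
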