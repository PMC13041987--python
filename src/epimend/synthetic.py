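"""Synthetic confluent epithelium: ground truth plus invertible corruption.

``simulate`` renders a drifting weighted-Voronoi (power-diagram)
tessellation with persistent seed identity, so the track table and lineage
are exact by construction.  Scheduled divisions grow the mother cell to a
programmed area ratio relative to its neighbors before replacing its seed
by two daughter seeds; scheduled extrusions shrink a cell to a small
apical area and remove it.  A junction-bright intensity render and an
event-probability movie (Gaussian bumps at true events) accompany the
labels.

``corrupt`` injects the typical segmentation/tracking errors -- false
splits, false merges, one-frame dropouts and track id swaps -- as a real
faulty pipeline would produce them (fragmenting the affected tracks), and
emits the exact inverse edit script: replaying it through
:func:`epimend.corrections.apply_script` restores the ground truth
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import LabelMovie, _junction_mask, region_table
from .io import EVENT_COLUMNS
from .tracking import tracks_from_labels

__all__ = [
    "SimParams",
    "CorruptionParams",
    "SimulationResult",
    "CorruptionResult",
    "simulate",
    "corrupt",
    "event_probability_movie",
]


@dataclass(frozen=True)
class SimParams:
    width: int = 160
    height: int = 160
    n_cells: int = 100
    n_frames: int = 30
    drift_sigma: float = 0.8
    n_divisions: int = 5
    n_extrusions: int = 5
    pre_division_growth: float = 1.5
    growth_frames: int = 5
    extrusion_shrink_frames: int = 6
    extrusion_final_area: float = 0.16  # fraction of mean cell area
    intensity_noise_sigma: float = 0.05
    seed: int = 1

    def __post_init__(self):
        if min(self.n_cells, self.n_frames) < 1 or self.n_divisions < 0 \
                or self.n_extrusions < 0:
            raise ValueError("invalid simulation sizes")
        n_ev = self.n_divisions + self.n_extrusions
        lo = max(self.growth_frames + 2, self.extrusion_shrink_frames + 1)
        if n_ev and self.n_frames - 3 - lo + 1 < n_ev:
            raise ValueError(
                f"cannot schedule {n_ev} events in {self.n_frames} frames")


@dataclass(frozen=True)
class CorruptionParams:
    p_split: float = 0.02
    p_merge: float = 0.02
    p_dropout: float = 0.02
    p_swap: float = 0.02
    seed: int = 7

    def __post_init__(self):
        for p in (self.p_split, self.p_merge, self.p_dropout, self.p_swap):
            if not 0 <= p <= 1:
                raise ValueError("corruption probabilities must be in [0, 1]")


@dataclass
class SimulationResult:
    movie: LabelMovie
    tracks: pd.DataFrame
    events: pd.DataFrame
    intensity: np.ndarray
    params: SimParams


@dataclass
class CorruptionResult:
    movie: LabelMovie
    tracks: pd.DataFrame
    log: list[dict] = field(default_factory=list)
    inverse_script: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# rendering

def _power_assign(shape, pos, weights, ids, window=None, margin=0.0):
    """Label image of the power diagram: pixel -> id of the seed minimizing
    squared distance minus weight.  With ``window=(y0, y1, x0, x1)`` only
    that sub-image is rendered, using the seeds within ``margin`` of it."""
    if window is None:
        H, W = shape
        y0 = x0 = 0
        y1, x1 = H, W
        sel = slice(None)
    else:
        y0, y1, x0, x1 = window
        sel = ((pos[:, 0] >= y0 - margin) & (pos[:, 0] < y1 + margin)
               & (pos[:, 1] >= x0 - margin) & (pos[:, 1] < x1 + margin))
    p = pos[sel].astype(np.float32)
    w = weights[sel].astype(np.float32)
    yy, xx = np.mgrid[y0:y1, x0:x1].astype(np.float32)
    cost = ((yy[None] - p[:, 0, None, None]) ** 2
            + (xx[None] - p[:, 1, None, None]) ** 2
            - w[:, None, None])
    return np.asarray(ids)[sel][np.argmin(cost, axis=0)].astype(np.int32)


def _cleanup_frame(lab):
    """Reattach stray rasterization orphans (a label's non-largest
    4-connected components) to their dominant 4-neighbor label."""
    from scipy import ndimage as ndi
    from skimage import measure as skm
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for _ in range(4):
        cc = skm.label(lab, connectivity=1, background=0)
        n_comp = cc.max()
        counts = np.bincount(cc.ravel(), minlength=n_comp + 1)
        # largest component of each label keeps it; others are orphans
        lab_of_comp = ndi.labeled_comprehension(
            lab, cc, np.arange(1, n_comp + 1), lambda v: v[0], int, 0)
        best: dict[int, tuple[int, int]] = {}
        for comp in range(1, n_comp + 1):
            l = int(lab_of_comp[comp - 1])
            sz = int(counts[comp])
            if l not in best or (sz, -comp) > best[l][:2]:
                best[l] = (sz, -comp, comp)
        orphan_comps = [c for c in range(1, n_comp + 1)
                        if best[int(lab_of_comp[c - 1])][2] != c]
        if not orphan_comps:
            return lab
        for comp in orphan_comps:
            mask = cc == comp
            ring = ndi.binary_dilation(mask, structure=four) & ~mask
            vals = lab[ring]
            vals = vals[(vals > 0) & (vals != lab[mask][0])]
            if vals.size:
                counts_n = np.bincount(vals)
                lab[mask] = int(counts_n.argmax())
    return lab


def _areas_and_neighbors(lab):
    areas = np.bincount(lab.ravel())
    pairs = set()
    for a, b in ((lab[:, :-1], lab[:, 1:]), (lab[:-1, :], lab[1:, :])):
        m = a != b
        pa, pb = a[m], b[m]
        pairs.update(zip(np.minimum(pa, pb).tolist(), np.maximum(pa, pb).tolist()))
    neigh: dict[int, list[int]] = {}
    for a, b in pairs:
        neigh.setdefault(a, []).append(b)
        neigh.setdefault(b, []).append(a)
    return areas, neigh


def _ratio_of(lab, cell_id):
    areas, neigh = _areas_and_neighbors(lab)
    ns = neigh.get(cell_id, [])
    if not ns:
        return math.nan
    return areas[cell_id] / (sum(areas[n] for n in ns) / len(ns))


def _solve_weight(shape, pos, weights, ids, idx, objective, target, span,
                  r_cell: float, idx2: int | None = None):
    """Monotone bisection of one seed weight so that ``objective`` (a
    function of the locally re-rendered label image) hits ``target``
    within 1.5%.  With ``idx2`` the same weight is applied to both seeds
    (used to size a daughter pair as one unit)."""
    w = weights.copy()
    H, W = shape
    cy, cx = pos[idx]
    half = 5.0 * r_cell
    window = (max(0, int(cy - half)), min(H, int(cy + half) + 1),
              max(0, int(cx - half)), min(W, int(cx + half) + 1))

    def f(wi):
        w[idx] = wi
        if idx2 is not None:
            w[idx2] = wi
        return objective(_power_assign(shape, pos, w, ids,
                                       window=window, margin=3.0 * r_cell))

    lo, hi = weights[idx] - span, weights[idx] + span
    flo, fhi = f(lo), f(hi)
    # the span doubles as a per-frame rate limit: if the target is out of
    # reach this frame, move as far as allowed and let the ramp catch up
    if fhi <= target:
        return hi
    if flo >= target:
        return lo
    best = weights[idx]
    for _ in range(14):
        mid = 0.5 * (lo + hi)
        val = f(mid)
        best = mid
        if abs(val - target) <= 0.015 * abs(target):
            break
        if val < target:
            lo = mid
        else:
            hi = mid
    return best


def _poisson_disk(rng, n, width, height, min_dist):
    pts = []
    attempts = 0
    d2 = min_dist * min_dist
    while len(pts) < n and attempts < 50000:
        p = (rng.uniform(0, height), rng.uniform(0, width))
        attempts += 1
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= d2 for q in pts):
            pts.append(p)
        if attempts % 10000 == 0:
            d2 *= 0.8  # relax if packing stalls
    if len(pts) < n:
        raise RuntimeError("could not place seeds")
    return np.array(pts)


def simulate(params: SimParams | None = None) -> SimulationResult:
    """Render a ground-truth movie; labels are track ids by construction."""
    p = params or SimParams()
    rng = np.random.default_rng(p.seed)
    H, W = p.height, p.width
    a_mean = W * H / p.n_cells
    r_cell = math.sqrt(a_mean / math.pi)
    pos = _poisson_disk(rng, p.n_cells, W, H, 0.75 * math.sqrt(a_mean))
    ids = np.arange(1, p.n_cells + 1)
    weights = np.zeros(p.n_cells)

    # --- schedule events on interior cells, unique frames, spatially
    # separated when temporally adjacent
    n_ev = p.n_divisions + p.n_extrusions
    margin = 3.5 * r_cell
    interior = [i for i in range(p.n_cells)
                if margin <= pos[i, 0] <= H - margin
                and margin <= pos[i, 1] <= W - margin]
    lo = max(p.growth_frames + 2, p.extrusion_shrink_frames + 1)
    hi = p.n_frames - 3
    ev_cells: list[int] = []
    ev_frames: list[int] = []
    for _ in range(2000):
        if len(ev_cells) == n_ev:
            break
        i = int(rng.choice(interior))
        t = int(rng.integers(lo, hi + 1))
        if i in ev_cells or t in ev_frames:
            continue
        ok = True
        for j, tj in zip(ev_cells, ev_frames):
            d = math.hypot(*(pos[i] - pos[j]))
            if abs(t - tj) <= 1 and d < 6.5 * r_cell:
                ok = False
                break
        if ok:
            ev_cells.append(i)
            ev_frames.append(t)
    if len(ev_cells) < n_ev:
        raise RuntimeError("could not schedule events")
    div_of = {ev_cells[k]: ev_frames[k] for k in range(p.n_divisions)}
    ext_of = {ev_cells[k]: ev_frames[k]
              for k in range(p.n_divisions, n_ev)}

    # mutable per-seed state
    id_list = ids.tolist()
    pos = pos.copy()
    weights = weights.copy()
    t_div = {id_list[i]: t for i, t in div_of.items()}   # id -> daughters appear
    t_ext = {id_list[i]: t for i, t in ext_of.items()}   # id -> last visible
    ext_start_area: dict[int, float] = {}
    next_id = p.n_cells + 1

    frames = []
    parents: dict[int, int] = {}
    div_daughters: dict[int, tuple[int, int, int]] = {}  # parent -> (t, d1, d2)
    mother_area: dict[int, int] = {}
    shape = (H, W)
    yy_grid, xx_grid = np.mgrid[0:H, 0:W]

    for t in range(p.n_frames):
        if t > 0 and p.drift_sigma > 0:
            # Lloyd-style relaxation toward the previous frame's centroids
            # keeps the tessellation regular (no cell gets squeezed away),
            # then Gaussian drift adds the per-frame motion
            prev = frames[-1]
            areas_prev = np.bincount(prev.ravel(),
                                     minlength=int(max(id_list)) + 1)
            ysum = np.bincount(prev.ravel(), weights=yy_grid.ravel(),
                               minlength=int(max(id_list)) + 1)
            xsum = np.bincount(prev.ravel(), weights=xx_grid.ravel(),
                               minlength=int(max(id_list)) + 1)
            for i, cid in enumerate(id_list):
                if areas_prev[cid] > 0:
                    cen = np.array([ysum[cid], xsum[cid]]) / areas_prev[cid]
                    pos[i] = pos[i] + 0.5 * (cen - pos[i])
        if t > 0:
            pos = pos + rng.normal(0.0, p.drift_sigma, pos.shape)
        # extruded cells disappear after their last visible frame
        for cid, te in list(t_ext.items()):
            if t == te + 1:
                k = id_list.index(cid)
                id_list.pop(k)
                pos = np.delete(pos, k, axis=0)
                weights = np.delete(weights, k)
                del t_ext[cid]
        # divisions: replace the mother seed by two daughter seeds at the
        # half-centroids of her region (balanced split by construction);
        # daughters inherit the grown weight so the territory is conserved
        for cid, td in list(t_div.items()):
            if t == td:
                k = id_list.index(cid)
                region = frames[-1] == cid
                ys, xs = np.nonzero(region)
                cy, cx = ys.mean(), xs.mean()
                best = None
                for _ in range(8):
                    theta = rng.uniform(0, math.pi)
                    side = ((ys - cy) * -math.sin(theta)
                            + (xs - cx) * math.cos(theta)) >= 0
                    bal = side.mean()
                    if best is None or abs(bal - 0.5) < abs(best[1] - 0.5):
                        best = (side, bal)
                    if 0.45 <= bal <= 0.55:
                        break
                side = best[0]
                c1 = np.array([ys[side].mean(), xs[side].mean()])
                c2 = np.array([ys[~side].mean(), xs[~side].mean()])
                d1, d2 = next_id, next_id + 1
                next_id += 2
                w_child = max(weights[k] - float(((c1 - c2) / 2) @ ((c1 - c2) / 2)),
                              0.0)
                id_list[k] = d1
                pos[k] = c1
                weights[k] = w_child
                id_list.append(d2)
                pos = np.vstack([pos, c2])
                weights = np.append(weights, w_child)
                parents[d1] = parents[d2] = cid
                div_daughters[cid] = (td, d1, d2)
                mother_area[cid] = int(region.sum())
                del t_div[cid]
        # inherited daughter weights relax back to neutral
        for cid, (td, d1, d2) in div_daughters.items():
            if t > td:
                for d in (d1, d2):
                    if d in id_list:
                        i = id_list.index(d)
                        step = min(abs(weights[i]) * 0.25, 0.15 * a_mean)
                        weights[i] = (weights[i] - math.copysign(step, weights[i])
                                      if abs(weights[i]) > 5 else 0.0)
        idarr = np.asarray(id_list)

        # calibrate dividing mothers (area ratio ramp) and extruding cells
        # (absolute area ramp down)
        for cid, td in t_div.items():
            k0 = td - p.growth_frames
            if k0 <= t < td:
                frac = (t - k0 + 1) / p.growth_frames
                target = 1.0 + (p.pre_division_growth - 1.0) * frac
                i = id_list.index(cid)
                weights[i] = _solve_weight(
                    shape, pos, weights, idarr, i,
                    lambda lab: _ratio_of(lab, cid), target,
                    span=0.1 * a_mean, r_cell=r_cell)
        for cid, te in t_ext.items():
            k0 = te - p.extrusion_shrink_frames + 1
            if k0 <= t <= te:
                if cid not in ext_start_area:
                    base = _power_assign(shape, pos, weights, idarr)
                    ext_start_area[cid] = float(np.bincount(
                        base.ravel(), minlength=cid + 1)[cid])
                a0 = ext_start_area[cid]
                a1 = p.extrusion_final_area * a_mean
                frac = (t - k0 + 1) / p.extrusion_shrink_frames
                target = a0 * (a1 / a0) ** frac
                i = id_list.index(cid)
                weights[i] = _solve_weight(
                    shape, pos, weights, idarr, i,
                    lambda lab: float(np.bincount(
                        lab.ravel(), minlength=cid + 1)[cid]),
                    target, span=0.15 * a_mean, r_cell=r_cell)
        # one-time sizing of newborn daughters: together they take (just
        # under) the mother's territory, split evenly -- so neither
        # resembles the mother's area and the tracker cannot link across
        # the division
        for cid, (td, d1, d2) in div_daughters.items():
            if td == t:
                i1, i2 = id_list.index(d1), id_list.index(d2)

                def combined(lab, a=d1, b=d2):
                    cnt = np.bincount(lab.ravel(), minlength=max(a, b) + 1)
                    return float(cnt[a] + cnt[b])

                def share(lab, a=d1, b=d2):
                    cnt = np.bincount(lab.ravel(), minlength=max(a, b) + 1)
                    return float(cnt[a]) / max(float(cnt[a] + cnt[b]), 1.0)
                w_pair = _solve_weight(
                    shape, pos, weights, idarr, i1, combined,
                    0.92 * mother_area[cid], span=0.5 * a_mean,
                    r_cell=r_cell, idx2=i2)
                weights[i1] = weights[i2] = w_pair
                weights[i1] = _solve_weight(
                    shape, pos, weights, idarr, i1, share, 0.5,
                    span=0.3 * a_mean, r_cell=r_cell)

        # support starving bystanders so drift squeeze never collapses a
        # cell to (near) zero pixels, which would fragment its own track
        lab0 = _power_assign(shape, pos, weights, idarr)
        areas0 = np.bincount(lab0.ravel(), minlength=int(idarr.max()) + 1)
        daughters_now = {d for (_, dd1, dd2) in div_daughters.values()
                         for d in (dd1, dd2)}
        adjusted = False
        for i, cid in enumerate(id_list):
            if cid in t_ext or cid in daughters_now:
                continue
            if areas0[cid] < 0.28 * a_mean:
                weights[i] = _solve_weight(
                    shape, pos, weights, idarr, i,
                    lambda lab, c=cid: float(np.bincount(
                        lab.ravel(), minlength=c + 1)[c]),
                    0.35 * a_mean, span=0.15 * a_mean, r_cell=r_cell)
                adjusted = True
            elif weights[i] > 0 and cid not in t_div \
                    and areas0[cid] > 0.5 * a_mean:
                weights[i] = max(weights[i] - 0.15 * a_mean, 0.0)
                adjusted = True
        if adjusted:
            lab0 = _power_assign(shape, pos, weights, idarr)
        lab = _cleanup_frame(lab0)
        frames.append(lab)

    movie = LabelMovie(np.stack(frames), pixel_size=1.0, frame_interval=1.0)
    tracks = tracks_from_labels(movie, parents)

    # --- event table
    ev_rows = []
    eid = 1
    cent = {(int(r.frame), int(r.track_id)): (float(r.y), float(r.x))
            for r in tracks.itertuples()}
    for cid, (td, d1, d2) in sorted(div_daughters.items()):
        (y1, x1), (y2, x2) = cent[(td, d1)], cent[(td, d2)]
        ev_rows.append({"event_id": eid, "kind": "division", "frame": td,
                        "y": (y1 + y2) / 2, "x": (x1 + x2) / 2,
                        "parent_track": cid, "daughter_a": min(d1, d2),
                        "daughter_b": max(d1, d2)})
        eid += 1
    for i, te in sorted(ext_of.items()):
        cid = int(ids[i])
        y, x = cent[(te, cid)]
        ev_rows.append({"event_id": eid, "kind": "extrusion", "frame": te,
                        "y": y, "x": x, "parent_track": cid,
                        "daughter_a": 0, "daughter_b": 0})
        eid += 1
    events = pd.DataFrame(ev_rows, columns=EVENT_COLUMNS)

    intensity = _render_intensity(movie, rng, p.intensity_noise_sigma)
    return SimulationResult(movie, tracks, events, intensity, p)


def _render_intensity(movie: LabelMovie, rng, noise_sigma: float) -> np.ndarray:
    from scipy.ndimage import gaussian_filter
    out = np.empty(movie.data.shape, dtype=np.float32)
    for t in range(movie.n_frames):
        sk = _junction_mask(movie.data[t]).astype(np.float32)
        img = gaussian_filter(sk, 1.3)
        if img.max() > 0:
            img /= img.max()
        img = img + rng.normal(0.0, noise_sigma, img.shape).astype(np.float32)
        out[t] = np.clip(img, 0.0, None)
    return out


def event_probability_movie(events: pd.DataFrame, shape: tuple[int, int, int],
                            kind: str | None = None, sigma: float = 2.5,
                            peak: float = 1.0) -> np.ndarray:
    """Probability movie with Gaussian bumps at the listed events (frame
    +/- 1, slightly damped off-frame) -- a stand-in for an external
    event-detection network."""
    T, H, W = shape
    prob = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[0:H, 0:W]
    for ev in events.itertuples():
        if kind is not None and ev.kind != kind:
            continue
        bump = peak * np.exp(-((yy - ev.y) ** 2 + (xx - ev.x) ** 2)
                             / (2 * sigma * sigma)).astype(np.float32)
        for dt, damp in ((-1, 0.8), (0, 1.0), (1, 0.8)):
            t = int(ev.frame) + dt
            if 0 <= t < T:
                np.maximum(prob[t], damp * bump, out=prob[t])
    return np.clip(prob, 0.0, 1.0)


# ---------------------------------------------------------------------------
# corruption

def _bbox_interior(regmap, lab, shape, margin=3):
    r = regmap.get(lab)
    if r is None:
        return False
    ymin, xmin, ymax, xmax = r.bbox
    H, W = shape
    return (ymin >= margin and xmin >= margin
            and ymax <= H - margin and xmax <= W - margin)


def _split_chord(mask, centroid, theta):
    """Partition a region by the chord through its centroid at angle
    ``theta``; returns (part_a, part_b) masks or None if unusable."""
    from scipy import ndimage as ndi
    ys, xs = np.nonzero(mask)
    side = ((ys - centroid[0]) * (-math.sin(theta))
            + (xs - centroid[1]) * math.cos(theta)) >= 0
    part_a = np.zeros_like(mask)
    part_a[ys[side], xs[side]] = True
    part_b = mask & ~part_a
    if not part_a.any() or not part_b.any():
        return None
    four = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for part in (part_a, part_b):
        _, n = ndi.label(part, structure=four)
        if n != 1:
            return None
    bal = part_a.sum() / mask.sum()
    if not 0.4 <= bal <= 0.6:
        return None
    return part_a, part_b


class _Locks:
    """Spatio-temporal exclusion zones for corruption sampling."""

    def __init__(self):
        self.zones: list[tuple[int, int, float, float, float]] = []

    def add(self, f0, f1, y, x, r):
        self.zones.append((f0, f1, y, x, r))

    def blocked(self, t, y, x):
        for f0, f1, zy, zx, zr in self.zones:
            if f0 <= t <= f1 and math.hypot(y - zy, x - zx) <= zr:
                return True
        return False


def corrupt(movie: LabelMovie, tracks: pd.DataFrame,
            params: CorruptionParams | None = None) -> CorruptionResult:
    """Inject segmentation/tracking errors with their exact inverses.

    Per-(frame, cell) draws select split / merge / dropout / swap
    injections.  Track fragmentation mimics an erroneous pipeline: a split
    interrupts the victim's track (one end, two nearby starts -- the
    classic false-division signature), merges and dropouts fragment the
    victim's identity.  Sites near track starts/ends (i.e. real events)
    or near other injections are left untouched so that every inverse is
    exact and injections are independent; replaying ``inverse_script``
    restores the input bit-for-bit.
    """
    cp = params or CorruptionParams()
    rng = np.random.default_rng(cp.seed)
    M = movie.data.copy()
    T = movie.n_frames
    shape = movie.frame_shape
    out_movie = LabelMovie(M, pixel_size=movie.pixel_size,
                           frame_interval=movie.frame_interval)

    locks = _Locks()
    # protect real events: every interior track start/end is one
    g = tracks.groupby("track_id")
    first = g.first()
    last = g.last()
    for tid, row in first.iterrows():
        if row.frame > 0:
            locks.add(int(row.frame) - 4, int(row.frame) + 4,
                      float(row.y), float(row.x), 45.0)
    for tid, row in last.iterrows():
        if row.frame < T - 1:
            locks.add(int(row.frame) - 4, int(row.frame) + 4,
                      float(row.y), float(row.x), 45.0)

    next_fresh = int(max(M.max(), tracks.track_id.max() if len(tracks) else 0)) + 1
    log: list[dict] = []
    inverse: list[dict] = []
    p1, p2 = cp.p_split, cp.p_split + cp.p_merge
    p3, p4 = p2 + cp.p_dropout, p2 + cp.p_dropout + cp.p_swap

    t_range = range(1, T - 1) if T >= 3 else range(T)
    for t in t_range:
        regs = {r.label: r for r in region_table(out_movie, t)}
        med_area = float(np.median([r.area for r in regs.values()])) if regs else 0.0
        for lab in sorted(regs):
            u = float(rng.random())
            if u >= p4:
                continue
            r = regs.get(lab)
            if r is None or not (out_movie.data[t] == lab).any():
                continue
            cy, cx = r.centroid
            interior_time = 0 < t < T - 1
            if interior_time:
                if locks.blocked(t, cy, cx):
                    continue
                if not _bbox_interior(regs, lab, shape):
                    continue
                present_adj = ((M[t - 1] == lab).any()
                               and (M[t + 1] == lab).any())
            else:
                present_adj = False

            if u < p1:
                done = _inject_split(out_movie, t, lab, r, med_area, rng,
                                     present_adj, next_fresh, log, inverse)
            elif u < p2:
                done = _inject_merge(out_movie, t, lab, regs, locks, rng,
                                     present_adj, next_fresh, log, inverse,
                                     shape)
            elif u < p3:
                done = _inject_dropout(out_movie, t, lab, r, present_adj,
                                       next_fresh, log, inverse)
            else:
                done = _inject_swap(out_movie, t, lab, regs, locks,
                                    present_adj, log, inverse, shape)
            if done:
                next_fresh = int(max(next_fresh, out_movie.data.max() + 1))
                locks.add(t - 2, t + 2, cy, cx, 32.0)
                if done is not True:  # partner centroid to lock as well
                    locks.add(t - 2, t + 2, done[0], done[1], 32.0)

    corrupted_tracks = _derive_corrupted_tracks(out_movie, tracks)
    return CorruptionResult(out_movie, corrupted_tracks, log, inverse[::-1])


def _inject_split(mv, t, lab, r, med_area, rng, present_adj, fresh,
                  log, inverse):
    if r.area < med_area:
        return False
    mask = mv.data[t] == lab
    parts = None
    for _ in range(4):
        theta = float(rng.uniform(0, math.pi))
        parts = _split_chord(mask, r.centroid, theta)
        if parts is not None:
            break
    if parts is None:
        return False
    part_a, part_b = parts
    if present_adj:
        h1, h2 = fresh, fresh + 1
        sub = mv.data[t:]
        sub[sub == lab] = h1  # track interrupted from t on
        mv.data[t][part_b] = h2
        inverse.append({"op": "merge", "frame": int(t),
                        "label_a": int(h1), "label_b": int(h2)})
        log.append({"kind": "split", "frame": int(t), "label": int(lab),
                    "new_labels": [int(h1), int(h2)],
                    "y": r.centroid[0], "x": r.centroid[1]})
    else:
        h2 = fresh
        mv.data[t][part_b] = h2
        inverse.append({"op": "merge", "frame": int(t),
                        "label_a": int(lab), "label_b": int(h2)})
        log.append({"kind": "split", "frame": int(t), "label": int(lab),
                    "new_labels": [int(lab), int(h2)],
                    "y": r.centroid[0], "x": r.centroid[1]})
    return True


def _pick_partner(mv, t, lab, regs, locks, shape, want_min_dist=None):
    """Eligible neighbor of ``lab`` at frame t, by longest shared boundary
    (or farthest centroid when ``want_min_dist`` is set)."""
    img = mv.data[t]
    mask = img == lab
    from scipy import ndimage as ndi
    dil = ndi.binary_dilation(mask, structure=np.ones((3, 3)))
    cands = np.unique(img[dil & ~mask])
    cands = [int(c) for c in cands if c > 0 and c != lab]
    best, best_key = None, None
    r0 = regs[lab]
    for c in cands:
        rc = regs.get(c)
        if rc is None or not _bbox_interior(regs, c, shape):
            continue
        if locks.blocked(t, rc.centroid[0], rc.centroid[1]):
            continue
        if not ((mv.data[t - 1] == c).any() and (mv.data[t + 1] == c).any()):
            continue
        d = math.hypot(rc.centroid[0] - r0.centroid[0],
                       rc.centroid[1] - r0.centroid[1])
        if want_min_dist is not None:
            if d < want_min_dist:
                continue
            key = (d, -c)
        else:
            shared = int((ndi.binary_dilation(
                mask, structure=np.ones((3, 3))) & (img == c)).sum())
            key = (shared, -c)
        if best_key is None or key > best_key:
            best, best_key = c, key
    return best


def _inject_merge(mv, t, lab, regs, locks, rng, present_adj, fresh,
                  log, inverse, shape):
    if not present_adj:
        return False
    partner = _pick_partner(mv, t, lab, regs, locks, shape)
    if partner is None:
        return False
    img = mv.data[t]
    pix_a = np.argwhere(img == lab)
    pix_b = np.argwhere(img == partner)
    img[img == partner] = lab
    b2 = fresh
    sub = mv.data[t + 1:]
    sub[sub == partner] = b2  # victim's later identity fragments
    inverse.append({
        "op": "split_seeded", "frame": int(t), "label": int(lab),
        "seed_groups": [pix_a.tolist(), pix_b.tolist()]})
    rc = regs[partner]
    log.append({"kind": "merge", "frame": int(t), "label": int(lab),
                "absorbed": int(partner), "renamed_to": int(b2),
                "y": rc.centroid[0], "x": rc.centroid[1]})
    return (rc.centroid[0], rc.centroid[1])


def _inject_dropout(mv, t, lab, r, present_adj, fresh, log, inverse):
    if not present_adj:
        return False
    mask = mv.data[t] == lab
    ys, xs = np.nonzero(mask)
    # an interior point of the region to flood-fill from
    k = int(np.argmax((mask & np.roll(mask, 1, 0) & np.roll(mask, -1, 0)
                       & np.roll(mask, 1, 1) & np.roll(mask, -1, 1))[ys, xs]))
    py, px = int(ys[k]), int(xs[k])
    mv.data[t][mask] = 0
    l2 = fresh
    sub = mv.data[t + 1:]
    sub[sub == lab] = l2
    inverse.append({"op": "fill_hole", "frame": int(t), "y": py, "x": px})
    log.append({"kind": "dropout", "frame": int(t), "label": int(lab),
                "renamed_to": int(l2), "y": r.centroid[0], "x": r.centroid[1]})
    return True


def _inject_swap(mv, t, lab, regs, locks, present_adj, log, inverse, shape):
    if not present_adj:
        return False
    partner = _pick_partner(mv, t, lab, regs, locks, shape, want_min_dist=15.0)
    if partner is None:
        return False
    a, b = int(lab), int(partner)
    for f in range(t, mv.n_frames):
        ma = mv.data[f] == a
        mb = mv.data[f] == b
        mv.data[f][ma] = b
        mv.data[f][mb] = a
    inverse.append({"op": "swap_tracks", "frame_from": int(t),
                    "id_a": a, "id_b": b})
    rc = regs[partner]
    log.append({"kind": "swap", "frame": int(t), "label": a, "partner": b,
                "y": regs[lab].centroid[0], "x": regs[lab].centroid[1]})
    return (rc.centroid[0], rc.centroid[1])


def _derive_corrupted_tracks(mv: LabelMovie, gt_tracks: pd.DataFrame
                             ) -> pd.DataFrame:
    """Track table of the corrupted movie (labels are ids throughout);
    ground-truth lineage edges are kept only where both endpoints survived
    with their original timing."""
    plain = tracks_from_labels(mv)
    gt_par = {}
    for tid, grp in gt_tracks.groupby("track_id"):
        par = int(grp.parent_track.iloc[0])
        if par:
            gt_par[int(tid)] = (par, int(grp.frame.min()))
    g = plain.groupby("track_id")["frame"]
    first, last = g.min().to_dict(), g.max().to_dict()
    parents = {}
    for d, (par, t0) in gt_par.items():
        if d in first and par in last \
                and first[d] == t0 and last[par] == t0 - 1:
            parents[d] = par
    if parents:
        plain["parent_track"] = plain["track_id"].map(
            lambda tid: parents.get(int(tid), 0))
    return plain
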