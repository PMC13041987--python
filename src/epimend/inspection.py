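"""Suspicious-track flags: point curation effort where errors are likely.

A track is suspicious when it appears or disappears in the tissue interior
without a registered division/extrusion explaining it, when a cell property
(area, position) jumps between consecutive frames, or when the track is
very short.  Border tracks are exempt from appear/disappear flags because
cells legitimately enter and leave the field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FlagConfig", "flag_suspicious", "FLAG_COLUMNS"]

FLAG_COLUMNS = ["track_id", "frame", "kind", "detail"]


@dataclass(frozen=True)
class FlagConfig:
    flag_appear: bool = True
    flag_disappear: bool = True
    flag_area_jump: bool = True
    area_jump_ratio: float = 1.5
    flag_short_track: bool = True
    min_track_len: int = 2
    flag_position_jump: bool = True
    max_displacement: float = 12.0
    border_margin: int = 2

    def __post_init__(self):
        if self.area_jump_ratio <= 1:
            raise ValueError("area_jump_ratio must be > 1")


def _event_exemptions(events: pd.DataFrame | None):
    daughters: set[int] = set()
    parents: set[int] = set()
    extruding: set[int] = set()
    if events is not None and len(events):
        div = events[events.kind == "division"]
        daughters.update(div.daughter_a.astype(int))
        daughters.update(div.daughter_b.astype(int))
        parents.update(div.parent_track.astype(int))
        extruding.update(
            events.loc[events.kind == "extrusion", "parent_track"].astype(int))
    return daughters, parents, extruding


def flag_suspicious(movie, tracks: pd.DataFrame,
                    events: pd.DataFrame | None = None,
                    cfg: FlagConfig | None = None) -> pd.DataFrame:
    """Flag unexpected appearance/disappearance and sudden property changes.

    ``events`` lists registered divisions/extrusions: their parents and
    daughters are legitimate track ends/starts and are not flagged.
    Flags are sorted by (frame, track_id).
    """
    cfg = cfg or FlagConfig()
    t_last = movie.n_frames - 1
    daughters, parents, extruding = _event_exemptions(events)
    flags: list[dict] = []

    for tid, grp in tracks.groupby("track_id"):
        grp = grp.sort_values("frame")
        first, last = grp.iloc[0], grp.iloc[-1]
        duration = len(grp)
        if cfg.flag_appear and first.frame > 0 and not first.touches_border \
                and tid not in daughters:
            flags.append({"track_id": int(tid), "frame": int(first.frame),
                          "kind": "appear",
                          "detail": f"starts at frame {int(first.frame)} in the interior"})
        if cfg.flag_disappear and last.frame < t_last and not last.touches_border \
                and tid not in parents and tid not in extruding:
            flags.append({"track_id": int(tid), "frame": int(last.frame),
                          "kind": "disappear",
                          "detail": f"ends at frame {int(last.frame)} in the interior"})
        if cfg.flag_short_track and duration < cfg.min_track_len:
            flags.append({"track_id": int(tid), "frame": int(first.frame),
                          "kind": "short_track",
                          "detail": f"duration {duration} < {cfg.min_track_len}"})
        if duration >= 2:
            area_exempt = tid in extruding  # registered shrink
            areas = grp.area.to_numpy(dtype=float)
            frames = grp.frame.to_numpy()
            ys, xs = grp.y.to_numpy(), grp.x.to_numpy()
            for k in range(duration - 1):
                if cfg.flag_area_jump and not area_exempt \
                        and areas[k] > 0 and areas[k + 1] > 0:
                    ratio = max(areas[k], areas[k + 1]) / min(areas[k], areas[k + 1])
                    if ratio > cfg.area_jump_ratio:
                        flags.append({
                            "track_id": int(tid), "frame": int(frames[k + 1]),
                            "kind": "area_jump",
                            "detail": f"area {areas[k]:.0f} -> {areas[k + 1]:.0f}"})
                if cfg.flag_position_jump:
                    step = float(np.hypot(ys[k + 1] - ys[k], xs[k + 1] - xs[k]))
                    ngap = max(1, int(frames[k + 1] - frames[k]))
                    if step / ngap > cfg.max_displacement:
                        flags.append({
                            "track_id": int(tid), "frame": int(frames[k + 1]),
                            "kind": "position_jump",
                            "detail": f"moved {step:.1f} px in {ngap} frame(s)"})
    df = pd.DataFrame(flags, columns=FLAG_COLUMNS)
    return df.sort_values(["frame", "track_id"], ignore_index=True)
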