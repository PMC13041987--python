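"""Before/after curation quality metrics.

All four are signed, with perfect values (1, 0, 0, 0) exactly when the
two movies agree up to a label permutation:

* skeleton_iou     -- IoU of the binary junction skeletons, pooled over
                      all frames (single ratio, not a per-frame mean);
* cell_nb_error    -- (N_after - N_before) / N_after over total region
                      counts, whole movie, regardless of tracks;
* length_track_error -- relative error of the mean track duration;
* area_track_error -- relative error of the mean cell area along tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import pandas as pd

from .core import LabelMovie, skeletonize_frame
from .errors import GeometryError

__all__ = [
    "CurationReport",
    "skeleton_iou",
    "cell_nb_error",
    "length_track_error",
    "area_track_error",
    "curation_report",
]


@dataclass(frozen=True)
class CurationReport:
    skeleton_iou: float
    cell_nb_error: float
    length_track_error: float
    area_track_error: float

    def as_dict(self) -> dict:
        return asdict(self)


def _check_geometry(a: LabelMovie, b: LabelMovie):
    if a.data.shape != b.data.shape:
        raise GeometryError(
            f"movie geometries differ: {a.data.shape} vs {b.data.shape}")


def skeleton_iou(movie_before: LabelMovie, movie_after: LabelMovie) -> float:
    """IoU of the two junction-skeleton movies; both empty -> 1.0."""
    _check_geometry(movie_before, movie_after)
    inter = union = 0
    for t in range(movie_before.n_frames):
        sb = skeletonize_frame(movie_before, t)
        sa = skeletonize_frame(movie_after, t)
        inter += int((sb & sa).sum())
        union += int((sb | sa).sum())
    return inter / union if union else 1.0


def _count_cells(movie: LabelMovie) -> int:
    return sum(int(movie.labels_in_frame(t).size) for t in range(movie.n_frames))


def cell_nb_error(movie_before: LabelMovie, movie_after: LabelMovie) -> float:
    """(N_after - N_before) / N_after on total region counts."""
    _check_geometry(movie_before, movie_after)
    n_after = _count_cells(movie_after)
    if n_after == 0:
        raise ValueError("after-movie contains no cells")
    return (n_after - _count_cells(movie_before)) / n_after


def _mean_duration(tracks: pd.DataFrame) -> float:
    if tracks.empty:
        raise ValueError("empty track table")
    return float(tracks.groupby("track_id").size().mean())


def length_track_error(tracks_before: pd.DataFrame,
                       tracks_after: pd.DataFrame) -> float:
    """(mean duration after - before) / after."""
    after = _mean_duration(tracks_after)
    return (after - _mean_duration(tracks_before)) / after


def area_track_error(tracks_before: pd.DataFrame,
                     tracks_after: pd.DataFrame) -> float:
    """(mean area along tracks after - before) / after, over all
    (frame, label) observations."""
    if tracks_before.empty or tracks_after.empty:
        raise ValueError("empty track table")
    after = float(tracks_after["area"].mean())
    before = float(tracks_before["area"].mean())
    return (after - before) / after


def curation_report(movie_before: LabelMovie, movie_after: LabelMovie,
                    tracks_before: pd.DataFrame,
                    tracks_after: pd.DataFrame) -> CurationReport:
    return CurationReport(
        skeleton_iou=skeleton_iou(movie_before, movie_after),
        cell_nb_error=cell_nb_error(movie_before, movie_after),
        length_track_error=length_track_error(tracks_before, tracks_after),
        area_track_error=area_track_error(tracks_before, tracks_after),
    )
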