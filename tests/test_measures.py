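import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epimend.core import LabelMovie
from epimend.measures import (cell_features, group_from_track_intensity,
                              perimeter_polygonal, temporal_table,
                              track_features)
from epimend.tracking import tracks_from_labels
from test_core import hex_tiling


def square_movie(side=10, pad=4):
    size = side + 2 * pad
    frame = np.ones((size, size), dtype=np.int32)  # background cell 1
    frame[pad:pad + side, pad:pad + side] = 2
    return LabelMovie(frame[None])


class TestCellFeatures:
    def test_square_area_and_shape_index(self):
        feats = cell_features(square_movie(), which=["area", "shape_index"])
        sq = feats[feats.label == 2].iloc[0]
        assert sq.area == 100
        assert sq.shape_index == pytest.approx(4.0, rel=0.05)

    def test_disk_shape_index_near_lower_bound(self):
        from skimage.draw import disk
        frame = np.ones((40, 40), dtype=np.int32)
        rr, cc = disk((20, 20), 11.3)
        frame[rr, cc] = 2
        feats = cell_features(LabelMovie(frame[None]), which=["shape_index"])
        si = feats[feats.label == 2].shape_index.iloc[0]
        assert si == pytest.approx(2 * math.sqrt(math.pi), rel=0.05)

    def test_hexagon_shape_index(self):
        from skimage.draw import polygon
        s = 12.0
        ang = np.arange(6) * np.pi / 3
        frame = np.ones((40, 40), dtype=np.int32)
        rr, cc = polygon(20 + s * np.sin(ang), 20 + s * np.cos(ang))
        frame[rr, cc] = 2
        feats = cell_features(LabelMovie(frame[None]), which=["shape_index"])
        si = feats[feats.label == 2].shape_index.iloc[0]
        assert si == pytest.approx(6 / math.sqrt(3 * math.sqrt(3) / 2), rel=0.05)

    def test_hexagonal_neighbors(self):
        movie = hex_tiling()
        feats = cell_features(movie, which=["NbNeighbor"])
        assert int(feats[feats.label == 6].NbNeighbor.iloc[0]) == 6

    def test_constant_intensity_field(self):
        movie = square_movie()
        inten = np.full(movie.data.shape, 3.25, dtype=np.float32)
        feats = cell_features(movie, intensity=inten,
                              which=["cytoplasmic_intensity",
                                     "junctional_intensity"])
        sq = feats[feats.label == 2].iloc[0]
        assert sq.cytoplasmic_intensity == pytest.approx(3.25)
        assert sq.junctional_intensity == pytest.approx(3.25)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            cell_features(square_movie(), which=["volume"])

    def test_area_conservation(self, sim1):
        feats = cell_features(sim1.movie, which=["area"])
        per_frame = feats.groupby("frame")["area"].sum()
        for t, total in per_frame.items():
            assert total == int((sim1.movie.data[t] > 0).sum())

    def test_orientation_range(self, sim1):
        feats = cell_features(sim1.movie, which=["orientation"])
        assert ((feats.orientation > -math.pi / 2 - 1e-9)
                & (feats.orientation <= math.pi / 2 + 1e-9)).all()


class TestTrackFeatures:
    def _df(self, centroids):
        rows = [{"track_id": 1, "frame": t, "label": 1, "y": y, "x": x,
                 "area": 10, "parent_track": 0, "touches_border": False}
                for t, (y, x) in enumerate(centroids)]
        return pd.DataFrame(rows)

    def test_collinear(self):
        tf = track_features(self._df([(0, 0), (0, 3), (0, 6)]))
        assert tf.avg_speed.iloc[0] == pytest.approx(3.0)
        assert tf.straightness.iloc[0] == pytest.approx(1.0)

    def test_return_trip(self):
        tf = track_features(self._df([(0, 0), (0, 3), (0, 0)]))
        assert tf.straightness.iloc[0] == pytest.approx(0.0)

    def test_three_four_five(self):
        tf = track_features(self._df([(0, 0), (3, 4), (3, 9)]))
        assert tf.avg_speed.iloc[0] == pytest.approx(5.0)
        assert tf.straightness.iloc[0] == pytest.approx(math.sqrt(90) / 10)

    def test_stationary_track_straightness_one(self):
        tf = track_features(self._df([(5, 5), (5, 5)]))
        assert tf.straightness.iloc[0] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=1, max_size=12))
    def test_straightness_in_unit_interval(self, centroids):
        tf = track_features(self._df(centroids))
        s = tf.straightness.iloc[0]
        assert 0.0 <= s <= 1.0 + 1e-9

    def test_duration_minutes(self, static_movie):
        tracks = tracks_from_labels(static_movie)
        tf = track_features(tracks, frame_interval=2.5)
        assert (tf.duration_min == 12.5).all()


class TestGroups:
    def _setup(self):
        movie = LabelMovie(np.stack([np.array([[1, 1], [2, 2]])] * 2).astype(np.int32))
        tracks = tracks_from_labels(movie)
        inten = np.zeros(movie.data.shape, np.float32)
        inten[:, 0, :] = 10.0
        inten[:, 1, :] = 100.0
        return movie, tracks, inten

    def test_mean_above_threshold(self):
        movie, tracks, inten = self._setup()
        g = group_from_track_intensity(movie, tracks, inten, threshold=50,
                                       stat="mean", direction="above",
                                       group_name="SO")
        assert g == {1: "", 2: "SO"}

    def test_threshold_below_min_selects_all(self):
        movie, tracks, inten = self._setup()
        g = group_from_track_intensity(movie, tracks, inten, threshold=-1)
        assert all(v for v in g.values())

    def test_above_below_partition(self):
        movie, tracks, inten = self._setup()
        above = group_from_track_intensity(movie, tracks, inten, 50,
                                           direction="above")
        below = group_from_track_intensity(movie, tracks, inten, 50,
                                           direction="below")
        for tid in above:
            assert bool(above[tid]) != bool(below[tid])


class TestTemporalTable:
    def test_constant_feature_flat_zero_ci(self):
        rows = pd.DataFrame([{"frame": t, "label": l, "area": 7.0}
                             for t in range(3) for l in (1, 2, 3)])
        table = temporal_table(rows, "area")
        assert (table["mean"] == 7.0).all()
        assert (table["ci95"] == 0.0).all()

    def test_n_below_two_has_no_ci(self):
        rows = pd.DataFrame([{"frame": 0, "label": 1, "area": 7.0}])
        table = temporal_table(rows, "area")
        assert math.isnan(table["ci95"].iloc[0])

    def test_disjoint_groups_never_overlap(self):
        rows = pd.DataFrame(
            [{"frame": t, "label": l, "area": 10.0 + l % 2, "group": "A" if l % 2 else "B"}
             for t in range(4) for l in range(6)])
        table = temporal_table(rows, "area", by_group=True)
        a = table[table.group == "A"]["mean"].to_numpy()
        b = table[table.group == "B"]["mean"].to_numpy()
        assert (a > b).all()

    def test_normal_ci_formula(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        rows = pd.DataFrame([{"frame": 0, "label": i, "area": v}
                             for i, v in enumerate(vals)])
        table = temporal_table(rows, "area")
        expected = 1.96 * np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert table["ci95"].iloc[0] == pytest.approx(expected)


class TestPerimeterEstimator:
    def test_rectangle_exact(self):
        mask = np.zeros((10, 16), bool)
        mask[2:8, 3:13] = True
        assert perimeter_polygonal(mask) == pytest.approx(32.0)

    def test_scales_linearly(self):
        small = np.zeros((14, 14), bool)
        small[2:12, 2:12] = True
        big = np.zeros((28, 28), bool)
        big[4:24, 4:24] = True
        assert perimeter_polygonal(big) == pytest.approx(
            2 * perimeter_polygonal(small))
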