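import numpy as np
import pytest

from epimend.core import LabelMovie, validate
from epimend.corrections import (apply_script, draw_junction, fill_hole,
                                 merge, remove_cell, set_track, split_seeded,
                                 swap_tracks)
from epimend.errors import EditError, ScriptError
from epimend.synthetic import CorruptionParams, corrupt
from epimend.tracking import tracks_from_labels


def movie_of(frame, n_frames=1):
    return LabelMovie(np.stack([np.asarray(frame, dtype=np.int32)] * n_frames))


class TestMerge:
    def test_two_by_two(self, two_cell_movie):
        movie, tracks = merge(two_cell_movie, None, 0, 1, 2)
        assert (movie.data[0] == 1).all()

    def test_area_bookkeeping_with_junction_gap(self):
        frame = np.zeros((6, 9), dtype=np.int32)
        frame[:, :4] = 1
        frame[:, 5:] = 2  # 1-px junction column between the regions
        area_a, area_b = 24, 24
        absorbed = 6
        movie, _ = merge(movie_of(frame), None, 0, 1, 2)
        assert int((movie.data[0] == 1).sum()) == area_a + area_b + absorbed

    def test_non_adjacent_refused(self):
        frame = np.zeros((6, 12), dtype=np.int32)
        frame[:, :3] = 1
        frame[:, 3:9] = 3
        frame[:, 9:] = 2
        with pytest.raises(EditError, match="not adjacent"):
            merge(movie_of(frame), None, 0, 1, 2)

    def test_cell_count_decreases_by_one(self, sim1):
        movie = sim1.movie.copy()
        from epimend.core import neighbor_graph
        a, b = neighbor_graph(movie, 0).edges()[0]
        before = movie.labels_in_frame(0).size
        movie, _ = merge(movie, sim1.tracks.copy(), 0, a, b)
        assert movie.labels_in_frame(0).size == before - 1


class TestSplitSeeded:
    def test_symmetric_rectangle(self):
        frame = np.zeros((2, 4), dtype=np.int32)
        frame[:, :] = 1
        movie = movie_of(frame)
        movie, _ = split_seeded(movie, None, 0, 1, seeds=[(0, 1), (0, 2)])
        left = movie.data[0][:, :2]
        right = movie.data[0][:, 2:]
        assert len(np.unique(left)) == 1 and len(np.unique(right)) == 1
        assert left[0, 0] != right[0, 0]
        assert {int(left[0, 0]), int(right[0, 0])} == {1, 2}

    def test_single_seed_is_error(self, two_cell_movie):
        with pytest.raises(EditError):
            split_seeded(two_cell_movie, None, 0, 1, seeds=[(0, 0)])

    def test_seed_outside_region_is_error(self, two_cell_movie):
        with pytest.raises(EditError):
            split_seeded(two_cell_movie, None, 0, 1, seeds=[(0, 0), (1, 1)])

    def test_parts_tile_the_region(self, sim1):
        movie = sim1.movie.copy()
        lab = int(movie.labels_in_frame(0)[10])
        mask = movie.data[0] == lab
        ys, xs = np.nonzero(mask)
        seeds = [(int(ys[0]), int(xs[0])), (int(ys[-1]), int(xs[-1]))]
        before = mask.sum()
        movie2, tracks2 = split_seeded(movie, sim1.tracks.copy(), 0, lab,
                                       seeds=seeds)
        labs_here = movie2.data[0][mask]
        assert len(np.unique(labs_here)) == 2
        assert (movie2.data[0][~mask] != labs_here.max()).all()
        assert int(np.isin(movie2.data[0], np.unique(labs_here)).sum()) == before


class TestDrawJunction:
    def test_vertical_split(self):
        frame = np.zeros((6, 8), dtype=np.int32)
        frame[:] = 4
        movie = movie_of(frame)
        movie, _ = draw_junction(movie, None, 0, [(0, 3), (5, 3)])
        labs = np.unique(movie.data[0])
        assert len(labs) == 2
        # confluence preserved in the dense representation
        assert validate(movie, confluent=True).ok

    def test_path_not_separating_is_error(self):
        frame = np.full((6, 8), 4, dtype=np.int32)
        with pytest.raises(EditError, match="does not separate"):
            draw_junction(movie_of(frame), None, 0, [(0, 3), (2, 3)])

    def test_path_crossing_two_cells_is_error(self, two_cell_movie):
        with pytest.raises(EditError, match="one cell"):
            draw_junction(two_cell_movie, None, 0, [(0, 0), (1, 1)])


class TestRemoveSwapSet:
    def test_remove_cell_truncates(self, static_movie):
        movie, tracks = remove_cell(static_movie, None, 3, 2)
        assert (movie.data[3:] != 2).all()
        assert (movie.data[:3] == static_movie.data[:3]).all()
        assert int(tracks[tracks.track_id == 2].frame.max()) == 2

    def test_remove_unknown_track_is_error(self, static_movie):
        with pytest.raises(EditError):
            remove_cell(static_movie, None, 0, 99)

    def test_remove_then_validate_non_confluent(self, static_movie):
        movie, _ = remove_cell(static_movie, None, 0, 1)
        assert validate(movie, confluent=False).ok

    def test_swap_is_involution(self, static_movie):
        original = static_movie.data.copy()
        movie, tracks = swap_tracks(static_movie, None, 2, 1, 2)
        assert not (movie.data == original).all()
        movie, tracks = swap_tracks(movie, tracks, 2, 1, 2)
        assert (movie.data == original).all()

    def test_swap_same_id_noop(self, static_movie):
        original = static_movie.data.copy()
        movie, _ = swap_tracks(static_movie, None, 0, 1, 1)
        assert (movie.data == original).all()

    def test_set_track_renames_tail(self, static_movie):
        movie, tracks = set_track(static_movie, None, 2, 2, 7)
        assert set(np.unique(movie.data[2:])) == {1, 7}
        assert set(np.unique(movie.data[:2])) == {1, 2}

    def test_fill_hole_restores_cell(self, static_movie):
        movie = static_movie.copy()
        movie.data[2][movie.data[2] == 2] = 0
        movie, tracks = fill_hole(movie, None, 2, 0, 6)
        assert (movie.data == static_movie.data).all()


class TestApplyScript:
    def test_empty_script_is_identity(self, sim1):
        movie = sim1.movie.copy()
        movie2, tracks2, log = apply_script(movie, sim1.tracks.copy(), [])
        assert (movie2.data == sim1.movie.data).all()
        assert log == []

    def test_bad_op_reports_position(self, static_movie):
        script = [
            {"op": "swap_tracks", "frame_from": 0, "id_a": 1, "id_b": 2},
            {"op": "swap_tracks", "frame_from": 0, "id_a": 1, "id_b": 2},
            {"op": "merge", "frame": 0, "label_a": 1, "label_b": 99},
        ]
        with pytest.raises(ScriptError) as err:
            apply_script(static_movie, None, script)
        assert err.value.position == 2

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_inverse_script_restores_ground_truth(self, sim_bank,
                                                  corrupt_bank, seed):
        sim = sim_bank(seed)
        cor = corrupt_bank(seed)
        assert len(cor.log) > 0
        movie, tracks, _ = apply_script(cor.movie.copy(), cor.tracks.copy(),
                                        cor.inverse_script)
        assert (movie.data == sim.movie.data).all()

    def test_operators_preserve_validity(self, sim1):
        movie = sim1.movie.copy()
        from epimend.core import neighbor_graph
        a, b = neighbor_graph(movie, 4).edges()[3]
        movie, tracks = merge(movie, sim1.tracks.copy(), 4, a, b)
        assert validate(movie, confluent=True).ok
        kept = min(a, b)
        mask = movie.data[4] == kept
        ys, xs = np.nonzero(mask)
        movie, tracks = split_seeded(
            movie, tracks, 4, kept,
            seeds=[(int(ys[0]), int(xs[0])), (int(ys[-1]), int(xs[-1]))])
        assert validate(movie, confluent=True).ok
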