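import math

import numpy as np
import pandas as pd
import pytest

from conftest import event_key
from epimend.errors import IntegrityError
from epimend.events import (EventParams, detect_divisions, detect_extrusions,
                            fate_groups, filter_events_by_probability,
                            relative_area_to_event)
from epimend.measures import cell_features
from epimend.synthetic import event_probability_movie


def track_df(rows):
    """rows: (track_id, frame, y, x, area[, touches_border])."""
    recs = []
    for r in rows:
        tid, frame, y, x, area = r[:5]
        recs.append({"track_id": tid, "frame": frame, "label": tid,
                     "y": float(y), "x": float(x), "area": int(area),
                     "parent_track": 0,
                     "touches_border": bool(r[5]) if len(r) > 5 else False})
    return pd.DataFrame(recs)


class TestDetectDivisions:
    def test_hand_example(self):
        rows = [(1, t, 10, 10, 100) for t in range(6)]           # parent ends t=5
        rows += [(2, 6, 8, 10, 50), (2, 7, 8, 10, 50)]           # starters t=6
        rows += [(3, 6, 12, 10, 50), (3, 7, 12, 10, 50)]
        rows += [(9, t, 40, 40, 100) for t in range(8)]          # full-length bystander
        div = detect_divisions(track_df(rows), EventParams(div_radius=6))
        assert len(div) == 1
        ev = div.iloc[0]
        assert (ev.parent_track, ev.frame) == (1, 6)
        assert (ev.daughter_a, ev.daughter_b) == (2, 3)
        assert (ev.y, ev.x) == (10.0, 10.0)  # midpoint of the daughters

    def test_one_starter_only_no_division(self):
        rows = [(1, t, 10, 10, 100) for t in range(6)]
        rows += [(2, 6, 8, 10, 50), (2, 7, 8, 10, 50)]
        rows += [(9, t, 40, 40, 100) for t in range(8)]
        div = detect_divisions(track_df(rows), EventParams(div_radius=6))
        assert div.empty

    @pytest.mark.parametrize("seed", [1, 4, 7])
    def test_uncorrupted_simulation_exact(self, sim_bank, seed):
        sim = sim_bank(seed)
        div = detect_divisions(sim.tracks)
        assert event_key(div) == event_key(sim.events[sim.events.kind == "division"])


class TestDetectExtrusions:
    def test_shrinking_track(self):
        rows = [(1, t, 10, 10, 100 - 15 * t) for t in range(7)]  # ends area 10
        rows += [(9, t, 40, 40, 100) for t in range(10)]
        ext = detect_extrusions(track_df(rows), detect_divisions(track_df(rows)),
                                EventParams(extrusion_area_max=20,
                                            extrusion_area_is_fraction=False))
        assert len(ext) == 1
        assert int(ext.iloc[0].parent_track) == 1
        assert int(ext.iloc[0].frame) == 6

    def test_large_final_area_not_extrusion(self):
        rows = [(1, t, 10, 10, 200) for t in range(7)]
        rows += [(9, t, 40, 40, 100) for t in range(10)]
        ext = detect_extrusions(track_df(rows), detect_divisions(track_df(rows)),
                                EventParams(extrusion_area_max=20,
                                            extrusion_area_is_fraction=False))
        assert ext.empty

    def test_border_exit_not_extrusion(self):
        rows = [(1, t, 10, 10, 10, True) for t in range(7)]
        rows += [(9, t, 40, 40, 100) for t in range(10)]
        ext = detect_extrusions(track_df(rows), detect_divisions(track_df(rows)),
                                EventParams(extrusion_area_max=20,
                                            extrusion_area_is_fraction=False))
        assert ext.empty

    @pytest.mark.parametrize("seed", [1, 4, 7])
    def test_uncorrupted_simulation_exact(self, sim_bank, seed):
        sim = sim_bank(seed)
        div = detect_divisions(sim.tracks)
        ext = detect_extrusions(sim.tracks, div)
        assert event_key(ext) == event_key(sim.events[sim.events.kind == "extrusion"])

    def test_no_track_is_both(self, sim_bank):
        sim = sim_bank(2)
        div = detect_divisions(sim.tracks)
        ext = detect_extrusions(sim.tracks, div)
        assert not set(div.parent_track) & set(ext.parent_track)


class TestProbabilityFilter:
    def test_constant_one_keeps_all(self, sim1):
        prob = np.ones(sim1.movie.data.shape, dtype=np.float32)
        kept = filter_events_by_probability(sim1.events, prob)
        assert len(kept) == len(sim1.events)

    def test_constant_zero_keeps_none(self, sim1):
        prob = np.zeros(sim1.movie.data.shape, dtype=np.float32)
        kept = filter_events_by_probability(sim1.events, prob)
        assert kept.empty

    def test_monotone_in_threshold(self, sim1, corrupt_bank):
        cor = corrupt_bank(1)
        div = detect_divisions(cor.tracks)
        prob = event_probability_movie(sim1.events, sim1.movie.data.shape)
        kept = {}
        for theta in (0.2, 0.5, 0.8):
            kept[theta] = set(filter_events_by_probability(
                div, prob, EventParams(prob_threshold=theta)).event_id)
        assert kept[0.8] <= kept[0.5] <= kept[0.2]

    def test_removes_false_divisions(self, sim_bank, corrupt_bank):
        sim, cor = sim_bank(3), corrupt_bank(3)
        div = detect_divisions(cor.tracks)
        gt = sim.events[sim.events.kind == "division"]
        assert len(div) > len(gt)
        prob = event_probability_movie(sim.events, sim.movie.data.shape)
        kept = filter_events_by_probability(div, prob)
        matched = 0
        for ev in kept.itertuples():
            assert any(abs(int(ev.frame) - int(g.frame)) <= 1
                       and math.hypot(ev.y - g.y, ev.x - g.x) <= 12
                       for g in gt.itertuples()), "false positive kept"
            matched += 1
        assert matched == len(gt)


class TestFateGroups:
    def test_terminal_semantics(self, sim1):
        groups = fate_groups(sim1.tracks, sim1.events)
        div_parents = set(sim1.events.loc[
            sim1.events.kind == "division", "parent_track"].astype(int))
        ext = set(sim1.events.loc[
            sim1.events.kind == "extrusion", "parent_track"].astype(int))
        for tid, g in groups.items():
            expected = ("Dividing" if tid in div_parents
                        else "Extruding" if tid in ext else "")
            assert g == expected

    def test_conflicting_fate_is_error(self):
        tracks = track_df([(1, t, 10, 10, 100) for t in range(3)])
        events = pd.DataFrame([
            {"event_id": 1, "kind": "division", "frame": 2, "y": 0, "x": 0,
             "parent_track": 1, "daughter_a": 2, "daughter_b": 3},
            {"event_id": 2, "kind": "extrusion", "frame": 2, "y": 0, "x": 0,
             "parent_track": 1, "daughter_a": 0, "daughter_b": 0}])
        with pytest.raises(IntegrityError):
            fate_groups(tracks, events)


class TestRelativeArea:
    def _features(self, tracks, neighbor_map):
        rows = []
        for r in tracks.itertuples():
            rows.append({"frame": int(r.frame), "label": int(r.label),
                         "track_id": int(r.track_id), "area": int(r.area),
                         "neighbors": neighbor_map.get(int(r.track_id), [])})
        return pd.DataFrame(rows)

    def test_equal_areas_constant_one(self):
        tracks = track_df([(i, t, 10 * i, 10, 100)
                           for i in (1, 2, 3) for t in range(5)])
        events = pd.DataFrame([{"event_id": 1, "kind": "extrusion", "frame": 4,
                                "y": 10, "x": 10, "parent_track": 1,
                                "daughter_a": 0, "daughter_b": 0}])
        feats = self._features(tracks, {1: [2, 3], 2: [1, 3], 3: [1, 2]})
        series = relative_area_to_event(events, feats)[1]
        assert list(series.ratio) == [1.0] * 5
        assert list(series.t_rel) == [-4, -3, -2, -1, 0]

    def test_mean_of_two_and_six(self):
        tracks = track_df([(1, 0, 0, 0, 4), (2, 0, 10, 0, 2), (3, 0, 0, 10, 6)])
        events = pd.DataFrame([{"event_id": 1, "kind": "extrusion", "frame": 0,
                                "y": 0, "x": 0, "parent_track": 1,
                                "daughter_a": 0, "daughter_b": 0}])
        feats = self._features(tracks, {1: [2, 3]})
        series = relative_area_to_event(events, feats)[1]
        assert series.ratio.iloc[0] == pytest.approx(1.0)  # 4 / mean(2, 6)

    def test_no_neighbors_missing_not_error(self):
        tracks = track_df([(1, 0, 0, 0, 4)])
        events = pd.DataFrame([{"event_id": 1, "kind": "extrusion", "frame": 0,
                                "y": 0, "x": 0, "parent_track": 1,
                                "daughter_a": 0, "daughter_b": 0}])
        feats = self._features(tracks, {1: []})
        series = relative_area_to_event(events, feats)[1]
        assert math.isnan(series.ratio.iloc[0])

    def test_programmed_growth_recovered(self, sim1):
        feats = cell_features(sim1.movie, which=["area", "neighbors"],
                              tracks=sim1.tracks)
        div = sim1.events[sim1.events.kind == "division"]
        series = relative_area_to_event(div, feats)
        finals = [s[s.t_rel == -1].ratio.iloc[0] for s in series.values()]
        for f in finals:
            assert f == pytest.approx(1.5, rel=0.10)
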