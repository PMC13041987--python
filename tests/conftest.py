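import numpy as np
import pytest

from epimend.core import LabelMovie
from epimend.synthetic import (CorruptionParams, SimParams, corrupt, simulate)

#: seeds used by the multi-seed acceptance properties
SEEDS = list(range(1, 21))


@pytest.fixture(scope="session")
def sim_bank():
    """Memoised simulations so the 20-seed properties pay for each
    simulation once across the whole session."""
    cache = {}

    def get(seed: int, **kw):
        key = (seed, tuple(sorted(kw.items())))
        if key not in cache:
            cache[key] = simulate(SimParams(seed=seed, **kw))
        return cache[key]

    return get


@pytest.fixture(scope="session")
def corrupt_bank(sim_bank):
    """Memoised corruptions of the banked simulations (corruption seed is
    decoupled from the tissue seed)."""
    cache = {}

    def get(seed: int):
        if seed not in cache:
            sim = sim_bank(seed)
            cache[seed] = corrupt(sim.movie, sim.tracks,
                                  CorruptionParams(seed=100 + seed))
        return cache[seed]

    return get


@pytest.fixture(scope="session")
def sim1(sim_bank):
    return sim_bank(1)


@pytest.fixture
def two_cell_movie():
    """Smallest confluent tiling: [[1, 1], [2, 2]]."""
    return LabelMovie(np.array([[[1, 1], [2, 2]]], dtype=np.int32))


@pytest.fixture
def static_movie():
    """Two static cells over 5 frames."""
    frame = np.zeros((8, 8), dtype=np.int32)
    frame[:, :4] = 1
    frame[:, 4:] = 2
    return LabelMovie(np.stack([frame] * 5))


def tracks_partition(tracks):
    """Canonical partition of (frame, label) observations into tracks."""
    groups = {}
    for r in tracks.itertuples():
        groups.setdefault(r.track_id, []).append((int(r.frame), int(r.label)))
    return sorted(tuple(sorted(v)) for v in groups.values())


def lineage_edges(tracks):
    return {(int(g.parent_track.iloc[0]), int(tid))
            for tid, g in tracks.groupby("track_id")
            if int(g.parent_track.iloc[0])}


def event_key(events):
    return sorted(zip(events.frame.astype(int),
                      events.parent_track.astype(int),
                      events.daughter_a.astype(int),
                      events.daughter_b.astype(int)))
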