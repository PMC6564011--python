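import numpy as np
import pandas as pd
import pytest

from chunklab import actions_frame, GameRecord


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_game(types, t_ms=None, game_id="g1", league=3, species="Terran"):
    """Small helper: build a GameRecord from a type sequence."""
    types = list(types)
    if t_ms is None:
        t_ms = np.arange(len(types)) * 100
    return GameRecord(game_id=game_id, league=league, species=species,
                      actions=actions_frame(t_ms, types))


def make_annotated(types, latencies, in_chunk, is_first=None):
    """Annotated per-action frame as produced by the detect module."""
    in_chunk = np.asarray(in_chunk, dtype=bool)
    if is_first is None:
        is_first = in_chunk & ~np.concatenate(([False], in_chunk[:-1]))
    return pd.DataFrame({
        "action_type": list(types),
        "latency_ms": np.asarray(latencies, dtype=float),
        "in_chunk": in_chunk,
        "is_first_action": np.asarray(is_first, dtype=bool),
    })


@pytest.fixture
def paper_stream():
    """The eight-action example stream from the action typology."""
    return ["ScreenShift", "Select", "Train", "HotkeySelect",
            "RightClick", "RightClick", "RightClick", "Ability"]
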