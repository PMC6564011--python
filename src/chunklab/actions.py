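"""Core vocabulary and containers for timestamped action streams.

A game is an ordered stream of categorical actions by one player, each
stamped in integer milliseconds from game start.  Seven action types cover
everything a real-time-strategy player does with mouse and keyboard:
unit selection (by mouse or hotkey), production (``Train``), construction
(``Build``), the context-sensitive ``RightClick``, special ``Ability``
commands, and ``ScreenShift`` — the onset of a new view-screen fixation,
treated as a distinct action because it indexes an attentional shift.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The seven-type action typology, in canonical order.
ACTION_TYPES: tuple[str, ...] = (
    "Select",
    "HotkeySelect",
    "Train",
    "Build",
    "RightClick",
    "Ability",
    "ScreenShift",
)

ACTION_TYPE_SET = frozenset(ACTION_TYPES)

#: Types whose immediate repeats are dropped from n-gram tiles: long
#: uninterrupted strings of these are input artifacts (key auto-repeat) or
#: redundant spam with abnormally low latencies, not meaningful sequencing.
REPEAT_FILTER_TYPES = frozenset({"RightClick", "Train", "HotkeySelect"})

#: Skill levels: 1 (least skilled) .. 7 from ladder leagues, 8 = professional.
LEAGUES = tuple(range(1, 9))

#: Levels of the player-species nuisance factor (chosen race, with the
#: in-game "Random" choice resolved to the race actually played).
SPECIES_LEVELS: tuple[str, ...] = (
    "Terran",
    "Protoss",
    "Zerg",
    "RandomTerran",
    "RandomProtoss",
    "RandomZerg",
)

ACTION_COLUMNS = ["t_ms", "action_type", "latency_ms"]


def compute_latencies(t_ms: np.ndarray) -> np.ndarray:
    """Per-action latency: ms since the same player's previous action.

    The first action of a game has no predecessor; its latency is NaN
    (never zero — a zero would bias every latency mean downward).
    """
    t = np.asarray(t_ms, dtype=float)
    lat = np.empty_like(t)
    if len(t) == 0:
        return lat
    lat[0] = np.nan
    lat[1:] = np.diff(t)
    return lat


def actions_frame(t_ms, action_type) -> pd.DataFrame:
    """Build the canonical per-action frame, computing latencies."""
    df = pd.DataFrame({"t_ms": np.asarray(t_ms, dtype=np.int64),
                       "action_type": list(action_type)})
    df["latency_ms"] = compute_latencies(df["t_ms"].to_numpy())
    return df


@dataclass
class GameRecord:
    """One player's ordered action stream plus metadata.

    Attributes
    ----------
    game_id : str
        Opaque identifier.
    league : int
        Ordinal skill level 1–8 (8 = professional).
    species : str
        Player-species nuisance factor.
    actions : pandas.DataFrame
        Columns ``t_ms`` (int, nondecreasing), ``action_type`` (str, one of
        the seven types), ``latency_ms`` (float, NaN for the first action).
    """

    game_id: str
    league: int
    species: str
    actions: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.league not in LEAGUES:
            raise ValueError(f"league must be in 1..8, got {self.league!r}")
        df = self.actions
        missing = [c for c in ("t_ms", "action_type") if c not in df.columns]
        if missing:
            raise ValueError(f"actions frame missing columns {missing}")
        bad = set(df["action_type"]) - ACTION_TYPE_SET
        if bad:
            raise ValueError(f"unknown action types {sorted(bad)}")
        t = df["t_ms"].to_numpy()
        if len(t) and (np.any(t < 0) or np.any(np.diff(t) < 0)):
            raise ValueError(f"game {self.game_id}: timestamps must be "
                             "nonnegative and nondecreasing")
        if "latency_ms" not in df.columns:
            df = df.copy()
            df["latency_ms"] = compute_latencies(t)
            self.actions = df

    @property
    def a(self) -> int:
        """Total action count."""
        return len(self.actions)

    @property
    def action_types(self) -> np.ndarray:
        return self.actions["action_type"].to_numpy()


def stable_game_hash(game_id: str) -> int:
    """Deterministic 32-bit hash of a game id (for per-game RNG substreams)."""
    return zlib.crc32(str(game_id).encode("utf-8"))
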