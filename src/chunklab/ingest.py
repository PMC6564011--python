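"""Reading, validating, and assembling action logs.

The canonical on-disk format is a UTF-8 CSV with header
``game_id, league, species, t_ms, action_type`` — one row per action.
Raw screen-position samples (``game_id, t_ms, x, y``) are aggregated into
screen fixations with a dispersion-threshold (I-DT) algorithm; the onset of
each fixation becomes a ``ScreenShift`` action that is merged into the key
action stream.
"""
from __future__ import annotations

import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .actions import (
    ACTION_TYPE_SET,
    GameRecord,
    actions_frame,
    compute_latencies,
)

LOG_COLUMNS = ["game_id", "league", "species", "t_ms", "action_type"]


def read_action_log(
    path,
    *,
    sort: bool = False,
    frame_rate: float | None = None,
) -> list[GameRecord]:
    """Read a canonical action-log CSV into one :class:`GameRecord` per game.

    Parameters
    ----------
    path : path-like or file-like
        CSV with columns ``game_id, league, species, t_ms, action_type``.
    sort : bool
        If True, stably sort each game's rows by timestamp; otherwise
        non-monotone timestamps are a hard error.
    frame_rate : float, optional
        If given, the ``t_ms`` column is interpreted as engine frame counts
        and converted to integer milliseconds via ``round(t * 1000 / frame_rate)``.

    Raises
    ------
    ValueError
        On an unknown action-type string (the offending CSV line is named)
        or on non-monotone timestamps without ``sort=True``.
    """
    df = pd.read_csv(path, dtype={"game_id": str, "species": str,
                                  "action_type": str})
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"action log missing columns {missing}")

    bad = ~df["action_type"].isin(ACTION_TYPE_SET)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"unknown action_type {df['action_type'].iloc[i]!r} "
            f"at CSV line {i + 2}"  # +1 header, +1 one-based
        )

    if frame_rate is not None:
        df = df.copy()
        df["t_ms"] = np.rint(df["t_ms"].to_numpy(dtype=float)
                             * 1000.0 / frame_rate).astype(np.int64)

    games: list[GameRecord] = []
    for gid, g in df.groupby("game_id", sort=False):
        t = g["t_ms"].to_numpy()
        if np.any(np.diff(t) < 0):
            if not sort:
                raise ValueError(
                    f"game {gid}: timestamps not nondecreasing "
                    "(pass sort=True to sort stably)"
                )
            g = g.sort_values("t_ms", kind="stable")
        if len(g) == 0:  # pragma: no cover - unreachable from groupby
            warnings.warn(f"game {gid} is empty; retained")
        games.append(GameRecord(
            game_id=str(gid),
            league=int(g["league"].iloc[0]),
            species=str(g["species"].iloc[0]),
            actions=actions_frame(g["t_ms"].to_numpy(),
                                  g["action_type"].to_numpy()),
        ))
    return games


def write_action_log(games: Sequence[GameRecord], path) -> None:
    """Write games back to the canonical CSV (inverse of :func:`read_action_log`)."""
    frames = []
    for g in games:
        f = g.actions[["t_ms", "action_type"]].copy()
        f.insert(0, "game_id", g.game_id)
        f.insert(1, "league", g.league)
        f.insert(2, "species", g.species)
        frames.append(f)
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=LOG_COLUMNS))
    out.to_csv(path, index=False)


def aggregate_fixations(
    raw: pd.DataFrame,
    *,
    dispersion_threshold: float = 2.0,
    min_duration_ms: float = 250.0,
) -> pd.DataFrame:
    """Aggregate raw screen-position samples into fixation-onset events.

    Dispersion-threshold identification (I-DT): a window of consecutive
    samples is a fixation when its dispersion
    ``(max x − min x) + (max y − min y)`` stays within
    ``dispersion_threshold`` and it spans at least ``min_duration_ms``.
    Windows are grown greedily to maximal length; one ``ScreenShift`` event
    is emitted at each fixation's onset (the screen movement *between*
    fixations is represented by the next fixation's onset).

    .. warning::
       The default thresholds (2.0 position units, 250 ms) are uncalibrated
       placeholders; calibrate them against your telemetry's coordinate
       system before interpreting fixation counts.

    Parameters
    ----------
    raw : DataFrame with columns ``t_ms, x, y``, timestamps nondecreasing.

    Returns
    -------
    DataFrame with columns ``t_ms, action_type`` (all ``ScreenShift``).
    """
    if dispersion_threshold <= 0 or min_duration_ms <= 0:
        raise ValueError("dispersion_threshold and min_duration_ms must be positive")
    if len(raw) == 0:
        raise ValueError("raw screen-sample stream is empty")
    t = raw["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValueError("raw screen samples must be sorted by t_ms")
    x = raw["x"].to_numpy(dtype=float)
    y = raw["y"].to_numpy(dtype=float)

    n = len(t)
    onsets: list[int] = []
    i = 0
    while i < n:
        # smallest window [i..j] spanning min_duration
        j = i
        while j < n and t[j] - t[i] < min_duration_ms:
            j += 1
        if j >= n:
            break
        if _dispersion(x, y, i, j) <= dispersion_threshold:
            while j + 1 < n and _dispersion(x, y, i, j + 1) <= dispersion_threshold:
                j += 1
            onsets.append(i)
            i = j + 1
        else:
            i += 1
    return pd.DataFrame({
        "t_ms": np.asarray([t[i] for i in onsets], dtype=np.int64),
        "action_type": ["ScreenShift"] * len(onsets),
    })


def _dispersion(x, y, i, j) -> float:
    xs = x[i:j + 1]
    ys = y[i:j + 1]
    return float((xs.max() - xs.min()) + (ys.max() - ys.min()))


def merge_streams(
    key_actions: pd.DataFrame,
    screen_shifts: pd.DataFrame,
    *,
    game_id: str = "game",
    league: int = 1,
    species: str = "Terran",
) -> GameRecord:
    """Merge key actions and screen-shift events into one time-sorted stream.

    Both inputs must be sorted by ``t_ms``.  On an exact timestamp tie the
    key action is placed before the screen shift (fixed convention so that
    downstream n-grams are deterministic).  Latencies are recomputed on the
    merged stream.
    """
    for name, df in (("key_actions", key_actions), ("screen_shifts", screen_shifts)):
        if len(df) and np.any(np.diff(df["t_ms"].to_numpy()) < 0):
            raise ValueError(f"{name} must be sorted by t_ms")
    k = key_actions[["t_ms", "action_type"]].copy()
    k["_prio"] = 0
    s = screen_shifts[["t_ms", "action_type"]].copy()
    s["_prio"] = 1
    merged = pd.concat([k, s], ignore_index=True)
    merged = merged.sort_values(["t_ms", "_prio"], kind="stable")
    return GameRecord(
        game_id=game_id, league=league, species=species,
        actions=actions_frame(merged["t_ms"].to_numpy(),
                              merged["action_type"].to_numpy()),
    )


def game_latency_identity(game: GameRecord) -> bool:
    """Check that defined latencies sum to t(last) − t(first)."""
    t = game.actions["t_ms"].to_numpy()
    if len(t) < 2:
        return True
    lat = compute_latencies(t)
    return bool(np.isclose(np.nansum(lat), t[-1] - t[0]))
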