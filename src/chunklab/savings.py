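"""Time savings of chunked actions.

The time saving of a chunked action is the mean latency of *non-chunked*
actions of the same type within the same game, minus the action's own
latency — positive when the chunked action was faster.  A game's overall
savings is the sum of per-action savings, reported in seconds and split
into a first-action component (chunk initiations, classically slow) and an
inter-action component (subsequent within-chunk actions, classically fast).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

MS_PER_S = 1000.0


@dataclass
class SavingsSummary:
    """Per-game time savings, in seconds.

    ``total_savings_s == first_action_savings_s + inter_action_savings_s``
    by construction.  ``n_excluded`` counts chunked actions that could not
    be scored (undefined latency, or no same-type non-chunked baseline).
    """
    total_savings_s: float
    first_action_savings_s: float
    inter_action_savings_s: float
    n_chunked: int
    n_excluded: int


def type_baselines(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-type mean latency of non-chunked actions with defined latency.

    Types with no eligible action get no baseline row.  First actions of
    chunks are chunked, hence excluded from baselines by construction.
    """
    elig = annotated[~annotated["in_chunk"] & annotated["latency_ms"].notna()]
    return (elig.groupby("action_type", sort=True)["latency_ms"]
            .agg(baseline_ms="mean", n_baseline="count")
            .reset_index())


def per_action_savings(
    annotated: pd.DataFrame, baselines: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Savings of each scorable chunked action, in ms.

    ``savings_ms = baseline(type) − latency`` (positive = faster than the
    same-type non-chunked mean).  Chunked actions with undefined latency or
    whose type has no baseline are dropped here; callers count them via
    :func:`game_savings`.
    """
    if baselines is None:
        baselines = type_baselines(annotated)
    chunked = annotated[annotated["in_chunk"]].copy()
    merged = chunked.merge(baselines[["action_type", "baseline_ms"]],
                           on="action_type", how="left")
    merged.index = chunked.index
    ok = merged["latency_ms"].notna() & merged["baseline_ms"].notna()
    out = merged[ok].copy()
    out["savings_ms"] = out["baseline_ms"] - out["latency_ms"]
    return out


def game_savings(annotated: pd.DataFrame) -> SavingsSummary:
    """Sum per-action savings over one game, split first/inter, in seconds."""
    chunked = annotated[annotated["in_chunk"]]
    n_chunked = int(len(chunked))
    if n_chunked == 0:
        return SavingsSummary(0.0, 0.0, 0.0, 0, 0)
    scored = per_action_savings(annotated)
    n_excluded = n_chunked - len(scored)
    first = scored["is_first_action"]
    first_s = float(scored.loc[first, "savings_ms"].sum()) / MS_PER_S
    inter_s = float(scored.loc[~first, "savings_ms"].sum()) / MS_PER_S
    return SavingsSummary(
        total_savings_s=first_s + inter_s,
        first_action_savings_s=first_s,
        inter_action_savings_s=inter_s,
        n_chunked=n_chunked,
        n_excluded=int(n_excluded),
    )


def first_vs_inter_summary(annotated_games: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-game mean first-action and within-chunk inter-action latencies.

    Games with no chunked action of both kinds (with defined latency) are
    excluded and counted in a warning; the paired rows feed a paired t-test.
    "Inter-action" means non-first *chunked* actions (the within-chunk
    positions after initiation), not non-chunked actions.
    """
    rows = []
    n_excluded = 0
    for gid, ann in annotated_games.items():
        ch = ann[ann["in_chunk"] & ann["latency_ms"].notna()]
        first = ch.loc[ch["is_first_action"], "latency_ms"]
        inter = ch.loc[~ch["is_first_action"], "latency_ms"]
        if len(first) == 0 or len(inter) == 0:
            n_excluded += 1
            continue
        rows.append({"game_id": gid,
                     "first_action_latency_ms": float(first.mean()),
                     "inter_action_latency_ms": float(inter.mean())})
    if n_excluded:
        warnings.warn(f"{n_excluded} games without both first- and "
                      "inter-action latencies were excluded")
    return pd.DataFrame(rows, columns=["game_id", "first_action_latency_ms",
                                       "inter_action_latency_ms"])


def redundant_rightclick_latency(annotated: pd.DataFrame) -> float | None:
    """Mean inter-right-click latency of redundant right-click runs.

    A qualifying run is a maximal stretch of ≥ 2 consecutive RightClick
    actions whose immediate neighbours on both sides are ScreenShift or the
    stream boundary (repeated right-clicks punctuated by screen shifts
    usually override each other — they are redundant, so their speed-up with
    skill cannot reflect strategic value).  Each run's first latency is the
    approach to the run and is excluded; the mean of the remaining
    within-run latencies is returned, or None when no run qualifies.
    """
    types = annotated["action_type"].to_numpy()
    lat = annotated["latency_ms"].to_numpy()
    n = len(types)
    vals: list[float] = []
    i = 0
    while i < n:
        if types[i] != "RightClick":
            i += 1
            continue
        j = i
        while j + 1 < n and types[j + 1] == "RightClick":
            j += 1
        run_len = j - i + 1
        left_ok = i == 0 or types[i - 1] == "ScreenShift"
        right_ok = j == n - 1 or types[j + 1] == "ScreenShift"
        if run_len >= 2 and left_ok and right_ok:
            vals.extend(x for x in lat[i + 1:j + 1] if not np.isnan(x))
        i = j + 1
    if not vals:
        return None
    return float(np.mean(vals))
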