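"""Synthetic action-stream generator with ground truth.

The generator emulates the statistical structure the analysis assumes: a
player repeatedly either (a) emits one of a small repertoire of planted
chunk n-grams — a slow first action (planning) followed by fast subsequent
actions, the classic chunk timing signature, (b) emits an artifactual
repeat burst of RightClick/Train/HotkeySelect with abnormally low
latencies, or (c) emits a single action drawn iid from the player's
marginal type distribution.  Latency noise is lognormal (positive,
right-skewed).  Base speed follows a skill schedule interpolating
geometrically between a mean action latency of ≈1019 ms at skill level 1
and ≈234 ms at level 8; the base draw scale is solved so that the *observed*
mixture mean (chunks, bursts and noise included) hits the schedule.

Every simulated action carries ground-truth labels (chunk emission flags
and the analytic expected per-action time saving), which downstream
recovery tests treat as the oracle.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .actions import (
    ACTION_TYPES,
    REPEAT_FILTER_TYPES,
    SPECIES_LEVELS,
    GameRecord,
    actions_frame,
)

#: Observed mean action latency by skill level, ms (geometric interpolation
#: between the level-1 and level-8 anchors).
LEAGUE_LATENCY_ANCHORS = (1019.0, 234.0)

#: Mild multiplicative species offsets on latency (nuisance factor).
SPECIES_LATENCY_FACTORS = {
    "Terran": 1.00, "Protoss": 0.97, "Zerg": 1.03,
    "RandomTerran": 1.01, "RandomProtoss": 0.98, "RandomZerg": 1.02,
}

#: Default marginal action-type mix (right-click dominated, as in real
#: telemetry where movement/attack orders outnumber everything else).
DEFAULT_MARGINALS = {
    "Select": 0.20, "HotkeySelect": 0.12, "Train": 0.10, "Build": 0.04,
    "RightClick": 0.30, "Ability": 0.04, "ScreenShift": 0.20,
}

#: Default planted repertoire (ngram, per-draw usage rate): chunked actions
#: end up near 20% of the stream, the plateau seen across skill levels.
DEFAULT_REPERTOIRE = (
    (("ScreenShift", "Select"), 0.08),
    (("HotkeySelect", "Train"), 0.04),
    (("ScreenShift", "Select", "RightClick"), 0.02),
    (("Select", "Build", "RightClick", "ScreenShift"), 0.01),
)


def league_base_latency(league: int) -> float:
    """Target observed mean latency (ms) for a skill level, 1..8."""
    if league not in range(1, 9):
        raise ValueError(f"league must be in 1..8, got {league}")
    lo, hi = LEAGUE_LATENCY_ANCHORS
    return float(lo * (hi / lo) ** ((league - 1) / 7.0))


@dataclass
class PlayerProfile:
    """Generative parameters for one simulated player.

    ``first_action_multiplier`` (> 1) slows chunk initiations and
    ``within_chunk_multiplier`` (< 1) speeds subsequent within-chunk
    actions, relative to the per-type base scale; the defaults (1.28, 0.78)
    give roughly offsetting first/inter savings so net per-game savings is
    near zero.  ``latency_noise_sigma`` is the lognormal log-scale sd.
    """
    league: int
    species: str
    marginals: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    repertoire: tuple = DEFAULT_REPERTOIRE
    base_latency_ms: dict[str, float] | None = None
    first_action_multiplier: float = 1.28
    within_chunk_multiplier: float = 0.78
    latency_noise_sigma: float = 0.5
    repeat_run_rate: float = 0.05
    repeat_latency_multiplier: float = 0.30
    repeat_run_geom_p: float = 0.35

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.marginals.values()), 1.0, abs_tol=1e-9):
            raise ValueError("marginals must sum to 1")
        if any(p < 0 for p in self.marginals.values()):
            raise ValueError("marginals must be nonnegative")
        rates = [r for _, r in self.repertoire]
        if any(not 0 <= r <= 1 for r in rates) or sum(rates) + self.repeat_run_rate > 1:
            raise ValueError("usage rates and repeat_run_rate must be in "
                             "[0,1] and sum to at most 1")
        for g, _ in self.repertoire:
            if not 2 <= len(g) <= 4:
                raise ValueError(f"repertoire n-grams must have length 2-4, "
                                 f"got {g}")
        if min(self.first_action_multiplier, self.within_chunk_multiplier,
               self.repeat_latency_multiplier) <= 0:
            raise ValueError("latency multipliers must be positive")
        if self.base_latency_ms is None:
            base = self._calibrated_base()
            self.base_latency_ms = {t: base for t in ACTION_TYPES}

    def _calibrated_base(self) -> float:
        """Base draw scale so the observed mixture mean hits the schedule."""
        rates = [(len(g), r) for g, r in self.repertoire]
        p_single = 1.0 - sum(r for _, r in rates) - self.repeat_run_rate
        e_runlen = 1.0 + 1.0 / self.repeat_run_geom_p  # 1 + Geometric(p)
        e_len = (sum(L * r for L, r in rates)
                 + self.repeat_run_rate * e_runlen + p_single)
        e_mult = (sum(r * (self.first_action_multiplier
                           + self.within_chunk_multiplier * (L - 1))
                      for L, r in rates)
                  + self.repeat_run_rate
                  * (1.0 + self.repeat_latency_multiplier * (e_runlen - 1.0))
                  + p_single)
        noise_mean = math.exp(0.5 * self.latency_noise_sigma ** 2)
        target = (league_base_latency(self.league)
                  * SPECIES_LATENCY_FACTORS.get(self.species, 1.0))
        return target / (e_mult / e_len * noise_mean)

    def expected_saving_ms(self, action_type: str, is_first: bool) -> float:
        """Analytic expected saving of one planted chunk action.

        Exact when repeat bursts are disabled (bursts deflate same-type
        baselines, biasing the empirical baseline below the base scale).
        """
        mult = (self.first_action_multiplier if is_first
                else self.within_chunk_multiplier)
        noise_mean = math.exp(0.5 * self.latency_noise_sigma ** 2)
        return self.base_latency_ms[action_type] * noise_mean * (1.0 - mult)


def make_profile(league: int, seed: int, species: str | None = None,
                 **overrides) -> PlayerProfile:
    """Deterministic default profile for a (league, seed) pair."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, league]))
    if species is None:
        species = SPECIES_LEVELS[rng.integers(len(SPECIES_LEVELS))]
    profile = PlayerProfile(league=league, species=species)
    if overrides:
        valid = set(PlayerProfile.__dataclass_fields__)
        bad = set(overrides) - valid
        if bad:
            raise ValueError(f"unknown profile overrides {sorted(bad)}")
        profile = replace(profile, **overrides)
    return profile


TRUTH_COLUMNS = ["game_id", "index", "emitted_by_chunk", "chunk_id",
                 "is_first_of_emission", "expected_saving_ms"]


def simulate_game(
    profile: PlayerProfile,
    duration_ms: float,
    seed: int | np.random.Generator,
    game_id: str = "sim",
) -> tuple[GameRecord, pd.DataFrame]:
    """Simulate one game; returns the record and its ground-truth sidecar.

    Draws repeat until cumulative time exceeds ``duration_ms`` (an emission
    in progress is completed); timestamps are cumulative latencies rounded
    to integer ms.  Emissions never interleave.
    """
    if duration_ms <= 0:
        raise ValueError("duration_ms must be positive")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p = profile
    type_list = list(ACTION_TYPES)
    probs = np.array([p.marginals[t] for t in type_list])
    cum_probs = np.cumsum(probs)
    repeat_types = sorted(REPEAT_FILTER_TYPES)
    rates = np.array([r for _, r in p.repertoire])
    cum_rates = np.cumsum(rates) if len(rates) else np.array([])

    types: list[str] = []
    lats: list[float] = []
    truth: list[tuple] = []

    def noise() -> float:
        return float(rng.lognormal(mean=0.0, sigma=p.latency_noise_sigma))

    t_total = 0.0
    while t_total <= duration_ms:
        u = rng.random()
        if len(rates) and u < cum_rates[-1]:
            ci = int(np.searchsorted(cum_rates, u, side="right"))
            g = p.repertoire[ci][0]
            cid = "-".join(g)
            for j, a in enumerate(g):
                first = j == 0
                mult = (p.first_action_multiplier if first
                        else p.within_chunk_multiplier)
                lat = p.base_latency_ms[a] * mult * noise()
                types.append(a)
                lats.append(lat)
                truth.append((True, cid, first,
                              p.expected_saving_ms(a, first)))
                t_total += lat
        elif u < (cum_rates[-1] if len(rates) else 0.0) + p.repeat_run_rate:
            a = repeat_types[rng.integers(len(repeat_types))]
            run_len = 1 + int(rng.geometric(p.repeat_run_geom_p))
            for j in range(run_len):
                mult = 1.0 if j == 0 else p.repeat_latency_multiplier
                lat = p.base_latency_ms[a] * mult * noise()
                types.append(a)
                lats.append(lat)
                truth.append((False, "", False, 0.0))
                t_total += lat
        else:
            a = type_list[int(np.searchsorted(cum_probs, rng.random(),
                                              side="right"))]
            lat = p.base_latency_ms[a] * noise()
            types.append(a)
            lats.append(lat)
            truth.append((False, "", False, 0.0))
            t_total += lat

    t_ms = np.rint(np.cumsum(lats)).astype(np.int64)
    game = GameRecord(game_id=game_id, league=p.league, species=p.species,
                      actions=actions_frame(t_ms, types))
    truth_df = pd.DataFrame(truth, columns=TRUTH_COLUMNS[2:])
    truth_df.insert(0, "game_id", game_id)
    truth_df.insert(1, "index", np.arange(len(truth_df)))
    return game, truth_df


def null_stream(
    marginals: dict[str, float],
    a: int,
    seed: int | np.random.Generator,
    game_id: str = "null",
    league: int = 1,
    species: str = "Terran",
) -> GameRecord:
    """iid draws from the marginals with unit-latency timestamps.

    This is the detector's null hypothesis made flesh: a player who picks
    each action independently at random with their own type mix.
    """
    if a < 1:
        raise ValueError("a must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    type_list = list(ACTION_TYPES)
    probs = np.array([marginals.get(t, 0.0) for t in type_list])
    probs = probs / probs.sum()
    idx = rng.choice(len(type_list), size=a, p=probs)
    types = [type_list[i] for i in idx]
    return GameRecord(game_id=game_id, league=league, species=species,
                      actions=actions_frame(np.arange(a, dtype=np.int64),
                                            types))


def planted_stream(
    marginals: dict[str, float],
    ngram: tuple[str, ...],
    rate: float,
    a: int,
    seed: int | np.random.Generator,
    game_id: str = "planted",
    league: int = 1,
    species: str = "Terran",
) -> GameRecord:
    """iid blocks with a planted n-gram occupying ``rate`` of the tiles.

    The stream is built in blocks of ``len(ngram)`` actions — each block is
    the planted n-gram with probability ``rate``, else iid draws — so for
    tiling at n = len(ngram) the planted tile occupancy is exactly
    Binomial(``rate``).  Unit-latency timestamps.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    L = len(ngram)
    type_list = list(ACTION_TYPES)
    probs = np.array([marginals.get(t, 0.0) for t in type_list])
    probs = probs / probs.sum()
    types: list[str] = []
    while len(types) < a:
        if rng.random() < rate:
            types.extend(ngram)
        else:
            idx = rng.choice(len(type_list), size=L, p=probs)
            types.extend(type_list[i] for i in idx)
    types = types[:a]
    return GameRecord(game_id=game_id, league=league, species=species,
                      actions=actions_frame(np.arange(a, dtype=np.int64),
                                            types))


def simulate_cohort(
    league_sizes: dict[int, int],
    seed: int,
    duration_ms: float = 960_000.0,
    **profile_overrides,
) -> tuple[list[GameRecord], pd.DataFrame]:
    """Independent players per league; one game each, plus a truth sidecar.

    The default 16-minute duration leaves well over 200 actions on each
    side of the 10-minute mark at every skill level.
    """
    games: list[GameRecord] = []
    truths: list[pd.DataFrame] = []
    for league in sorted(league_sizes):
        size = league_sizes[league]
        if size < 0:
            raise ValueError("league sizes must be nonnegative")
        for i in range(size):
            ss = np.random.SeedSequence([seed, league, i])
            rng = np.random.default_rng(ss)
            profile = make_profile(league, seed=int(rng.integers(2 ** 31)),
                                   **profile_overrides)
            gid = f"L{league}P{i:03d}"
            game, truth = simulate_game(profile, duration_ms,
                                        rng, game_id=gid)
            games.append(game)
            truths.append(truth)
    truth_df = (pd.concat(truths, ignore_index=True) if truths
                else pd.DataFrame(columns=TRUTH_COLUMNS))
    return games, truth_df
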