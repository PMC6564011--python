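"""Prevalence-based chunk detection.

A chunk is an action n-gram (length 2–4) that occurs more often than the
base rates of its component actions predict.  Because action types have
very unequal base rates, raw sequence frequency is misleading; the detector
corrects for base rates with a binomial null and controls selection bias
with data splitting:

1. Tile the game into non-overlapping n-grams (a trailing remainder is
   discarded).  Tiles containing an immediately repeated RightClick, Train,
   or HotkeySelect are dropped (artifactual key-repeat / spam strings).
2. Randomly split the tiles into equal train and test halves.
3. Under the null that the player draws each action independently from the
   game's marginal type proportions, the count K of a given n-gram among n
   tiles is Binomial(n, p) with p the product of the marginal proportions
   of its component actions.  Compute the upper-tail p-value P(X ≥ K) for
   every distinct n-gram in the training half.
4. Nominate the (at most) five lowest-p n-grams per length; discard their
   training p-values (they are optimistically biased by the selection).
5. Recompute each nominee's p-value on the held-out test half; a nominee
   with test p < α (default 0.05) is confirmed as a chunk.
6. Repeat for lengths 2, 3, 4 (at most 15 chunks per game), then mark every
   sliding occurrence of every confirmed chunk in the full stream.  A
   marked action whose predecessor is unmarked (or that begins the game)
   is a *first action* — the classically slow chunk-initiation position.
"""
from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .actions import ACTION_TYPES, REPEAT_FILTER_TYPES, GameRecord, stable_game_hash

logger = logging.getLogger(__name__)

NGram = tuple[str, ...]


@dataclass(frozen=True)
class NGramTile:
    """One element of the non-overlapping n-gram partition of a stream."""
    actions: NGram
    start_index: int


@dataclass
class ChunkCandidate:
    """An n-gram nominated from the training tiles.

    ``pval_train`` is kept for diagnostics only; inference never uses it
    (it is biased optimistic by the lowest-p selection).
    """
    ngram: NGram
    K_train: int
    n_train: int
    p_null: float
    pval_train: float


@dataclass
class Chunk:
    """A candidate evaluated on the held-out test tiles."""
    ngram: NGram
    K_train: int
    n_train: int
    p_null: float
    K_test: int
    n_test: int
    pval_test: float
    confirmed: bool

    @property
    def length(self) -> int:
        return len(self.ngram)


@dataclass
class ChunkAnnotation:
    """Per-action chunk flags for one game.

    ``chunk_ids[i]`` lists the indices (into the owning chunk list) of every
    confirmed chunk with an occurrence covering action ``i``.
    """
    in_chunk: np.ndarray
    is_first_action: np.ndarray
    chunk_ids: list[tuple[int, ...]]

    @classmethod
    def empty(cls, n: int) -> "ChunkAnnotation":
        return cls(np.zeros(n, dtype=bool), np.zeros(n, dtype=bool),
                   [() for _ in range(n)])


@dataclass
class DetectorConfig:
    """Tuning parameters of the chunk detector.

    alpha : per-test significance level on the held-out half (strict <).
    max_candidates : nominees carried to the test half, per length.
    lengths : n-gram lengths analysed independently.
    min_tiles : a length is skipped when fewer retained tiles than this.
    seed : master seed; each (game, length) gets a derived substream.
    """
    alpha: float = 0.05
    max_candidates: int = 5
    lengths: tuple[int, ...] = (2, 3, 4)
    min_tiles: int = 4
    seed: int = 0


@dataclass
class DetectionResult:
    chunks: list[Chunk]
    annotation: ChunkAnnotation
    skipped_lengths: dict[int, str] = field(default_factory=dict)

    @property
    def confirmed(self) -> list[Chunk]:
        return [c for c in self.chunks if c.confirmed]


def tile_ngrams(actions: Sequence[str], n: int) -> list[NGramTile]:
    """Partition a stream into non-overlapping n-grams starting at 0, n, 2n…

    A trailing remainder of fewer than ``n`` actions is discarded, e.g. the
    sequence XYXY tiles into the two bigrams XY, XY.
    """
    if n not in (2, 3, 4):
        raise ValueError(f"n must be 2, 3 or 4, got {n}")
    actions = list(actions)
    return [NGramTile(tuple(actions[i:i + n]), i)
            for i in range(0, len(actions) - n + 1, n)]


def filter_repeat_tiles(tiles: Iterable[NGramTile]) -> list[NGramTile]:
    """Drop tiles containing an adjacent repeat of a restricted type.

    A tile is dropped iff two immediately adjacent positions hold the same
    action type and that type is RightClick, Train, or HotkeySelect; long
    uninterrupted strings of these carry artifactual, abnormally low
    latencies rather than meaningful sequencing.
    """
    out = []
    for tile in tiles:
        a = tile.actions
        if any(a[i] == a[i + 1] and a[i] in REPEAT_FILTER_TYPES
               for i in range(len(a) - 1)):
            continue
        out.append(tile)
    return out


def split_train_test(
    tiles: Sequence[NGramTile], rng: np.random.Generator
) -> tuple[list[NGramTile], list[NGramTile]]:
    """Seeded uniform random half/half partition of tiles.

    With an odd count the extra tile goes to the training half.  The split
    is reproducible from the generator state; within each half the original
    tile order is preserved.
    """
    m = len(tiles)
    if m < 2:
        raise ValueError("need at least 2 tiles to split")
    n_train = (m + 1) // 2
    perm = rng.permutation(m)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return [tiles[i] for i in train_idx], [tiles[i] for i in test_idx]


def marginal_proportions(game: GameRecord | Sequence[str]) -> dict[str, float]:
    """Marginal proportion of each action type over all *a* game actions.

    Computed before any tile dropping, so the null model describes the
    player's full action mix.
    """
    types = game.action_types if isinstance(game, GameRecord) else list(game)
    a = len(types)
    if a == 0:
        raise ValueError("empty game has no marginal proportions")
    counts = Counter(types)
    return {t: counts.get(t, 0) / a for t in ACTION_TYPES}


def ngram_null_probability(ngram: NGram, marginals: Mapping[str, float]) -> float:
    """Null probability of an n-gram: the product of its actions' marginals."""
    p = 1.0
    for t in ngram:
        p *= marginals[t]
    return p


def binomial_upper_pvalue(K: int, n: int, p: float) -> float:
    """Upper-tail binomial probability P(X ≥ K), X ~ Binomial(n, p)."""
    if not 0 <= K <= n:
        raise ValueError(f"need 0 <= K <= n, got K={K}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if K == 0:
        return 1.0
    return float(sps.binom.sf(K - 1, n, p))


def nominate_candidates(
    train_tiles: Sequence[NGramTile],
    marginals: Mapping[str, float],
    limit: int = 5,
) -> list[ChunkCandidate]:
    """Rank distinct training n-grams by training p-value; keep the top few.

    Ties at the cutoff break by higher training count, then lexicographic
    n-gram order, so nomination is deterministic.  Only n-grams actually
    observed in the training half are nominable.
    """
    if len(train_tiles) == 0:
        raise ValueError("training set is empty")
    n_train = len(train_tiles)
    counts = Counter(t.actions for t in train_tiles)
    cands = []
    for ngram, K in counts.items():
        p_null = ngram_null_probability(ngram, marginals)
        cands.append(ChunkCandidate(
            ngram=ngram, K_train=K, n_train=n_train, p_null=p_null,
            pval_train=binomial_upper_pvalue(K, n_train, p_null),
        ))
    cands.sort(key=lambda c: (c.pval_train, -c.K_train, c.ngram))
    return cands[:limit]


def confirm_chunks(
    candidates: Sequence[ChunkCandidate],
    test_tiles: Sequence[NGramTile],
    marginals: Mapping[str, float],
    alpha: float = 0.05,
) -> list[Chunk]:
    """Re-test nominees on the held-out tiles; confirm at test p < alpha.

    The test half is untouched by the nomination step, so these p-values
    are unbiased; confirmation uses a strict inequality.
    """
    n_test = len(test_tiles)
    counts = Counter(t.actions for t in test_tiles)
    out = []
    for c in candidates:
        K_test = counts.get(c.ngram, 0)
        pval = binomial_upper_pvalue(K_test, n_test, c.p_null)
        out.append(Chunk(
            ngram=c.ngram, K_train=c.K_train, n_train=c.n_train,
            p_null=c.p_null, K_test=K_test, n_test=n_test,
            pval_test=pval, confirmed=bool(pval < alpha),
        ))
    return out


def mark_chunked_actions(
    actions: Sequence[str], chunks: Sequence[Chunk]
) -> ChunkAnnotation:
    """Mark every sliding occurrence of every confirmed chunk in the stream.

    Occurrences may overlap each other and chunks of different lengths; the
    marked position sets are unioned and each action records all owning
    chunks.  An action is a *first action* iff it is marked and its
    predecessor is unmarked (or it begins the game) — so back-to-back chunk
    occurrences form one run with a single first action, which is how
    nested "superchunks" longer than four actions are accommodated.
    """
    actions = list(actions)
    n = len(actions)
    ann = ChunkAnnotation.empty(n)
    owners: list[list[int]] = [[] for _ in range(n)]
    for ci, chunk in enumerate(chunks):
        if not chunk.confirmed:
            continue
        g = chunk.ngram
        L = len(g)
        for i in range(n - L + 1):
            if tuple(actions[i:i + L]) == g:
                for j in range(i, i + L):
                    ann.in_chunk[j] = True
                    if ci not in owners[j]:
                        owners[j].append(ci)
    ann.chunk_ids = [tuple(o) for o in owners]
    ann.is_first_action = ann.in_chunk & ~np.concatenate(
        ([False], ann.in_chunk[:-1]))
    return ann


def detect_chunks(
    game: GameRecord, config: DetectorConfig | None = None
) -> DetectionResult:
    """Run the full detection procedure on one game.

    The procedure runs independently per length in ``config.lengths`` with
    a documented RNG substream per (game, length) derived from
    ``config.seed``, unions the confirmed chunks (at most
    ``max_candidates`` per length), and marks the stream.  Lengths with too
    few retained tiles are skipped with a logged reason; a fully skipped
    game yields an empty chunk list and an all-false annotation.
    """
    config = config or DetectorConfig()
    actions = list(game.action_types)
    marginals = marginal_proportions(actions)

    chunks: list[Chunk] = []
    skipped: dict[int, str] = {}
    gh = stable_game_hash(game.game_id)
    for li, n in enumerate(config.lengths):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, gh, n]))
        tiles = filter_repeat_tiles(tile_ngrams(actions, n))
        if len(tiles) < max(config.min_tiles, 2):
            skipped[n] = (f"only {len(tiles)} retained tiles "
                          f"(< {max(config.min_tiles, 2)})")
            logger.info("game %s: length %d skipped: %s",
                        game.game_id, n, skipped[n])
            continue
        train, test = split_train_test(tiles, rng)
        cands = nominate_candidates(train, marginals,
                                    limit=config.max_candidates)
        chunks.extend(confirm_chunks(cands, test, marginals,
                                     alpha=config.alpha))
    confirmed = [c for c in chunks if c.confirmed]
    ann = mark_chunked_actions(actions, confirmed)
    return DetectionResult(chunks=chunks, annotation=ann,
                           skipped_lengths=skipped)


def annotate_frame(game: GameRecord, annotation: ChunkAnnotation):
    """Per-action annotation table (the ``annotations.csv`` schema)."""
    df = game.actions.copy()
    df.insert(0, "game_id", game.game_id)
    df.insert(1, "index", np.arange(len(df)))
    df["in_chunk"] = annotation.in_chunk
    df["is_first_action"] = annotation.is_first_action
    return df


def chunks_frame(game: GameRecord, chunks: Sequence[Chunk]):
    """Per-chunk results table (the ``chunks.csv`` schema)."""
    import pandas as pd

    return pd.DataFrame([{
        "game_id": game.game_id,
        "ngram": "-".join(c.ngram),
        "length": c.length,
        "K_train": c.K_train,
        "n_train": c.n_train,
        "p_null": c.p_null,
        "K_test": c.K_test,
        "n_test": c.n_test,
        "pval_test": c.pval_test,
        "confirmed": c.confirmed,
    } for c in chunks])
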