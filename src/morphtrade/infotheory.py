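"""Within-word information profiles and memory-surprisal tradeoff curves.

The distance-``t`` information profile I_t is the mutual information between
symbols ``t`` positions apart, conditioned on the intervening symbols:

    I_t = I[w_i : w_{i-t} | w_{i-t+1} .. w_{i-1}].

A comprehender that retains predictive information from the last ``T``
positions pays a memory cost of at most ``sum_{t<=T} t * I_t`` bits (each
bit weighted by how long it must be held) and incurs an average surprisal
of at least ``S_inf + sum_{t>T} I_t``: information carried over distances
beyond ``T`` is simply lost.  Sweeping ``T`` traces the memory-surprisal
tradeoff curve; its area under the curve (AUC) measures how efficiently an
ordering concentrates predictive information at short distances
(*information locality*) — lower is better.

Estimation conventions (shared by the plug-in estimator and the exact
enumeration oracle, so that the two agree to numerical precision on
corpora that realize a distribution with exact multiplicities):

* Each word is an independent padded sequence; no cross-word context.
* Conditional distributions are stratified by position within the word
  (contexts at different positions are never pooled), with left boundary
  padding so every context is defined.
* The end symbol is a predicted position: how predictable word termination
  is from the preceding morphemes is part of the within-word information
  structure (presence/absence of affixes is informative about the root).
* The entropy ladder H_t is the expected total code length of a word
  (morphemes plus the end symbol), in bits per word:
  H_t = E[ sum_i -log2 P(w_i | w_{i-t}..w_{i-1}) ].  I_t = H_{t-1} - H_t,
  clipped at zero.

Under these conventions I_t is exactly zero beyond the reach of a Markov
source, invariant under symbol relabeling, and (for fixed-length string
distributions, where the end position is deterministic within its stratum)
invariant under string reversal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .ordering import SymbolSequence

__all__ = [
    "ItProfile",
    "TradeoffCurve",
    "CurvePoint",
    "StringDistribution",
    "estimate_entropy_ladder",
    "it_profile",
    "exact_it",
    "tradeoff_curve",
    "auc",
    "default_t_max",
    "BOS",
    "EOS",
]

BOS = "<bos>"
EOS = "<eos>"

PLUGIN = "plugin"
HELDOUT = "heldout"
EXACT = "exact"


@dataclass(frozen=True)
class ItProfile:
    """Entropy ladder H_0..H_T and the derived profile I_1..I_T (bits/word)."""

    t_max: int
    entropy_ladder: tuple[float, ...]
    it_values: tuple[float, ...]
    estimator_tag: str
    n_clipped: int = 0

    def __post_init__(self) -> None:
        if len(self.entropy_ladder) != self.t_max + 1:
            raise ValueError("entropy ladder must have t_max + 1 entries")
        if len(self.it_values) != self.t_max:
            raise ValueError("profile must have t_max entries")


@dataclass(frozen=True)
class CurvePoint:
    T: int
    memory_bits: float
    excess_surprisal_bits: float


@dataclass(frozen=True)
class TradeoffCurve:
    """Memory bound vs excess surprisal, swept over the horizon T.

    ``excess_surprisal_bits`` is the surprisal lower bound minus the
    listener-optimal surprisal ``s_inf_estimate`` (= H_{t_max}), so the
    curve ends at zero excess and its AUC depends only on I_1..I_{t_max}.
    """

    points: tuple[CurvePoint, ...]
    s_inf_estimate: float


@dataclass(frozen=True)
class StringDistribution:
    """An explicit finite probability table over symbol strings."""

    items: tuple[tuple[SymbolSequence, float], ...]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "items", tuple((tuple(s), float(p)) for s, p in self.items)
        )
        if not self.items:
            raise ValueError("empty distribution")
        seen = set()
        for s, p in self.items:
            if p <= 0:
                raise ValueError(f"non-positive probability for {s!r}")
            if s in seen:
                raise ValueError(f"duplicate string {s!r}")
            seen.add(s)
        total = math.fsum(p for _, p in self.items)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def reversed(self) -> "StringDistribution":
        return StringDistribution(
            tuple((tuple(reversed(s)), p) for s, p in self.items)
        )


def default_t_max(sequences: Iterable[SymbolSequence]) -> int:
    """Default horizon: longest word length + 1 (no I_t exists beyond it)."""
    return max(len(s) for s in sequences) + 1


def pad_sequence(seq: SymbolSequence, t_max: int) -> SymbolSequence:
    """Left boundary pads and the end pad, as used by the estimators."""
    return tuple(f"{BOS}{j}" for j in range(1, t_max + 1)) + tuple(seq) + (EOS,)


# ---------------------------------------------------------------------------
# plug-in core (shared by corpus estimation and the enumeration oracle)


def _plugin_ladder(
    sequences: Sequence[SymbolSequence],
    t_max: int,
    weights: np.ndarray,
) -> list[float]:
    """Position-stratified plug-in ladder, vectorized over all positions.

    Contexts are grown one symbol at a time and re-compressed to dense ids
    with ``np.unique``, so alphabet size never enters the key radix.
    """
    if any(len(s) == 0 for s in sequences):
        raise ValueError("sequences must be non-empty")
    sequences = [tuple(s) + (EOS,) for s in sequences]
    vocab: dict[str, int] = {}
    lens = np.array([len(s) for s in sequences], dtype=np.int64)
    n, lmax = len(sequences), int(lens.max())
    mat = np.zeros((n, lmax), dtype=np.int64)
    for r, seq in enumerate(sequences):
        for c, sym in enumerate(seq):
            code = vocab.setdefault(sym, len(vocab))
            mat[r, c] = code
    pad_code = len(vocab)

    mask = np.arange(lmax)[None, :] < lens[:, None]
    word_idx, pos_idx = np.nonzero(mask)  # pos_idx: 0-based position in word
    sym = mat[word_idx, pos_idx]
    wt = np.asarray(weights, dtype=np.float64)[word_idx]
    total_w = float(np.asarray(weights, dtype=np.float64).sum())

    ctx = pos_idx.copy()  # t = 0 stratum: position index alone
    ladder: list[float] = []
    for t in range(t_max + 1):
        key = ctx * np.int64(pad_code + 1) + sym
        _, inv_j = np.unique(key, return_inverse=True)
        joint_w = np.bincount(inv_j, weights=wt)
        _, inv_c = np.unique(ctx, return_inverse=True)
        ctx_w = np.bincount(inv_c, weights=wt)
        p = joint_w[inv_j] / ctx_w[inv_c]
        ladder.append(float(np.dot(wt, -np.log2(p)) / total_w))
        if t < t_max:
            back = pos_idx - (t + 1)
            prev = np.where(back >= 0, mat[word_idx, np.maximum(back, 0)], pad_code)
            key = ctx * np.int64(pad_code + 2) + prev
            _, ctx = np.unique(key, return_inverse=True)
    return ladder


# ---------------------------------------------------------------------------
# held-out estimation with absolute discounting


class _NGramTables:
    """Per-(position, context-length) count tables with absolute discounting."""

    def __init__(self, t_max: int, discount: float, vocab_size: int):
        self.t_max = t_max
        self.d = discount
        self.v = vocab_size
        # tables[t]: ctx tuple -> (total, {sym: count})
        self.tables: list[dict] = [dict() for _ in range(t_max + 1)]

    @staticmethod
    def _ctx(seq: SymbolSequence, i: int, t: int) -> tuple:
        # position stratum i (0-based) plus up to t preceding symbols
        return (i,) + tuple(seq[max(0, i - t) : i])

    def add(self, seq: SymbolSequence) -> None:
        for i, s in enumerate(seq):
            for t in range(self.t_max + 1):
                node = self.tables[t].setdefault(self._ctx(seq, i, t), [0, {}])
                node[0] += 1
                node[1][s] = node[1].get(s, 0) + 1

    def prob(self, seq: SymbolSequence, i: int, sym: str, t: int) -> float:
        """P(sym | position i, preceding t symbols), backing off recursively."""
        lower = 1.0 / self.v if t == 0 else self.prob(seq, i, sym, t - 1)
        node = self.tables[t].get(self._ctx(seq, i, t))
        if node is None:
            return lower
        total, counts = node
        c = counts.get(sym, 0)
        return max(c - self.d, 0.0) / total + self.d * len(counts) / total * lower


def _heldout_ladder(
    sequences: Sequence[SymbolSequence],
    t_max: int,
    k_folds: int,
    discount: float,
    seed: int,
) -> list[float]:
    if len(sequences) < k_folds:
        raise ValueError(
            f"held-out estimation needs at least k_folds={k_folds} sequences"
        )
    sequences = [tuple(s) + (EOS,) for s in sequences]
    vocab = {s for seq in sequences for s in seq}
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sequences))
    folds = np.array_split(order, k_folds)
    loss = np.zeros(t_max + 1)
    for f in range(k_folds):
        test = set(folds[f].tolist())
        tables = _NGramTables(t_max, discount, len(vocab))
        for j, seq in enumerate(sequences):
            if j not in test:
                tables.add(seq)
        for j in test:
            seq = sequences[j]
            for i, s in enumerate(seq):
                for t in range(t_max + 1):
                    loss[t] -= math.log2(tables.prob(seq, i, s, t))
    return (loss / len(sequences)).tolist()


# ---------------------------------------------------------------------------
# public API


def estimate_entropy_ladder(
    sequences: Sequence[SymbolSequence],
    t_max: int,
    estimator: str = PLUGIN,
    *,
    weights: Sequence[float] | None = None,
    k_folds: int = 10,
    discount: float = 0.5,
    seed: int = 0,
) -> list[float]:
    """Estimate H_0..H_{t_max} (bits per word) from linearized words.

    ``plugin`` uses maximum-likelihood conditional frequencies pooled over
    the corpus within each position stratum; ``heldout`` uses k-fold
    cross-entropy with absolute discounting (default d = 0.5) and recursive
    lower-order backoff.  *weights* allows type-collapsed corpora (one entry
    per distinct sequence, weighted by its token count).
    """
    sequences = list(sequences)
    if not sequences:
        raise ValueError("no sequences")
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    if estimator == PLUGIN:
        w = (
            np.ones(len(sequences))
            if weights is None
            else np.asarray(list(weights), dtype=np.float64)
        )
        if len(w) != len(sequences):
            raise ValueError("weights length mismatch")
        return _plugin_ladder(sequences, t_max, w)
    if estimator == HELDOUT:
        if weights is not None:
            raise ValueError("weights are only supported by the plugin estimator")
        return _heldout_ladder(sequences, t_max, k_folds, discount, seed)
    raise ValueError(f"unknown estimator {estimator!r}")


def it_profile(
    ladder: Sequence[float], estimator_tag: str = PLUGIN
) -> ItProfile:
    """Differences of the entropy ladder, clipped at zero.

    Plug-in ladders are nonincreasing by construction; held-out smoothing
    can produce small negative differences, which are clipped and counted.
    """
    ladder = [float(h) for h in ladder]
    if len(ladder) < 2:
        raise ValueError("ladder must have length >= 2")
    raw = [ladder[t - 1] - ladder[t] for t in range(1, len(ladder))]
    clipped = sum(1 for x in raw if x < 0)
    return ItProfile(
        t_max=len(ladder) - 1,
        entropy_ladder=tuple(ladder),
        it_values=tuple(max(0.0, x) for x in raw),
        estimator_tag=estimator_tag,
        n_clipped=clipped,
    )


def exact_it(
    dist: StringDistribution, t_max: int, max_positions: int = 2_000_000
) -> ItProfile:
    """Evaluate the I_t profile of an explicit string distribution exactly.

    Full enumeration of the joint distribution of padded windows, under the
    same conventions as the plug-in estimator; on a corpus realizing *dist*
    with exact multiplicities the two agree to numerical precision.
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    seqs = [s for s, _ in dist.items]
    size = sum(len(s) + 1 for s in seqs) * (t_max + 1)
    if size > max_positions:
        raise ValueError(
            f"enumeration table of {size} positions exceeds cap {max_positions}"
        )
    probs = np.array([p for _, p in dist.items])
    ladder = _plugin_ladder(seqs, t_max, probs)
    return it_profile(ladder, estimator_tag=EXACT)


def tradeoff_curve(profile: ItProfile) -> TradeoffCurve:
    """Memory bound and excess surprisal bound at every horizon T."""
    it = profile.it_values
    total = math.fsum(it)
    points = []
    mem = 0.0
    for T in range(profile.t_max + 1):
        if T > 0:
            mem += T * it[T - 1]
        excess = math.fsum(it[T:])
        points.append(CurvePoint(T, mem, excess))
    # exact zero at the horizon, immune to fsum rounding
    points[-1] = CurvePoint(profile.t_max, points[-1].memory_bits, 0.0)
    return TradeoffCurve(tuple(points), s_inf_estimate=profile.entropy_ladder[-1])


def auc(curve: TradeoffCurve) -> float:
    """Area under the piecewise-linear tradeoff curve (trapezoid rule).

    Integrates excess surprisal over memory from 0 to the final memory
    value; duplicate points (I_T = 0) contribute zero width.
    """
    pts = sorted(curve.points, key=lambda p: p.T)
    area = 0.0
    for a, b in zip(pts, pts[1:]):
        area += (b.memory_bits - a.memory_bits) * (
            a.excess_surprisal_bits + b.excess_surprisal_bits
        ) / 2.0
    return area
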