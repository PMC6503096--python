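"""Transition tables and information-theoretic measures of pattern streams.

An order-n transition table tallies joint counts over (context, next-offset)
pairs and derives three probability views:

* ``P(next | context)`` — the transitional probability (TP), a plain
  maximum-likelihood ratio ``count(context, next) / count(context)``.
  No smoothing is applied: phrases that never occur are *absent*, not events
  of probability zero.
* ``P(context)`` — the empirical context frequency within the analyzed unit.
* ``P(next)`` — the pooled next-offset marginal.

From these follow, all in bits (log base 2):

* information content ``IC = -log2 TP`` — the surprisal of one transition;
* conditional entropy ``H(next | context) = -Σ_c P(c) Σ_y P(y|c) log2 P(y|c)``
  — the model's residual uncertainty about the next offset (at order 0 this
  is the marginal entropy of the offset alphabet);
* mutual information ``MI = H(next) - H(next | context)`` — the uncertainty
  reduction the context affords, a proxy for the depth of the sequential
  dependence (defined for order >= 1 only).

Movement-level statistics are combined to piece level either by occurrence-
weighted averaging of per-phrase TPs, or — for entropy and MI — by pooling
the movements' counts into one piece-level table, the count-level analogue
of the same weighting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .encoding import PatternStream, RelativePattern

__all__ = [
    "TransitionTable",
    "UndefinedStatisticError",
    "estimate_table",
    "pool_tables",
    "information_content",
    "conditional_entropy",
    "mutual_information",
    "weighted_average_tp",
    "piece_phrase_tp",
    "PieceProfile",
    "piece_profiles",
]

Context = tuple[int, ...]


class UndefinedStatisticError(ValueError):
    """A statistic was requested where it has no defined value (e.g. empty table)."""


@dataclass
class TransitionTable:
    """Joint counts over (context, next) for one Markov order."""

    order: int
    counts: dict[tuple[Context, int], int] = field(default_factory=dict)

    # -- construction -------------------------------------------------------

    def add(self, context: Context, nxt: int, count: int = 1) -> None:
        if len(context) != self.order:
            raise ValueError(f"context length {len(context)} != order {self.order}")
        self.counts[(context, nxt)] = self.counts.get((context, nxt), 0) + count

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.counts)

    # -- probability views --------------------------------------------------

    def context_counts(self) -> dict[Context, int]:
        out: dict[Context, int] = {}
        for (ctx, _), c in self.counts.items():
            out[ctx] = out.get(ctx, 0) + c
        return out

    def context_probability(self, context: Context) -> float:
        total = self.total
        if total == 0:
            raise UndefinedStatisticError("empty table has no context distribution")
        return self.context_counts().get(context, 0) / total

    def conditional_probability(self, context: Context, nxt: int) -> float | None:
        """TP of (context -> next); None when the pair was never observed."""
        joint = self.counts.get((context, nxt), 0)
        if joint == 0:
            return None
        ctx_total = sum(c for (ctx, _), c in self.counts.items() if ctx == context)
        return joint / ctx_total

    def rows(self) -> dict[Context, dict[int, float]]:
        """Conditional distributions P(next | context) per observed context."""
        joint: dict[Context, dict[int, int]] = {}
        for (ctx, nxt), c in self.counts.items():
            row = joint.setdefault(ctx, {})
            row[nxt] = row.get(nxt, 0) + c
        out: dict[Context, dict[int, float]] = {}
        for ctx, row in joint.items():
            row_total = sum(row.values())
            out[ctx] = {nxt: c / row_total for nxt, c in row.items()}
        return out

    def next_marginal(self) -> dict[int, float]:
        total = self.total
        if total == 0:
            raise UndefinedStatisticError("empty table has no next-offset marginal")
        out: dict[int, float] = {}
        for (_, nxt), c in self.counts.items():
            out[nxt] = out.get(nxt, 0) + c
        return {nxt: c / total for nxt, c in out.items()}

    def pattern_count(self, pattern: RelativePattern) -> int:
        return self.counts.get((pattern.context, pattern.next), 0)


def estimate_table(streams: PatternStream | Iterable[PatternStream]) -> TransitionTable:
    """Tally one or several pattern streams (all of one order) into a table."""
    if isinstance(streams, PatternStream):
        streams = [streams]
    streams = list(streams)
    if not streams:
        raise ValueError("no streams given")
    orders = {s.order for s in streams}
    if len(orders) != 1:
        raise ValueError(f"streams mix orders {sorted(orders)}")
    table = TransitionTable(order=orders.pop())
    for stream in streams:
        for ctx, nxt in stream.pairs:
            table.add(ctx, nxt)
    return table


def pool_tables(tables: Sequence[TransitionTable]) -> TransitionTable:
    """Sum joint counts of several same-order tables into one."""
    orders = {t.order for t in tables}
    if len(orders) != 1:
        raise ValueError(f"tables mix orders {sorted(orders)}")
    pooled = TransitionTable(order=orders.pop())
    for t in tables:
        for (ctx, nxt), c in t.counts.items():
            pooled.add(ctx, nxt, c)
    return pooled


def information_content(tp: float) -> float:
    """Surprisal -log2(tp) in bits; tp must be in (0, 1]."""
    if not 0.0 < tp <= 1.0:
        raise UndefinedStatisticError(f"information content undefined for tp={tp}")
    return -math.log2(tp)


def conditional_entropy(table: TransitionTable) -> float:
    """H(next | context) in bits, with 0·log 0 := 0."""
    total = table.total
    if total == 0:
        raise UndefinedStatisticError("conditional entropy undefined for an empty table")
    ctx_counts = table.context_counts()
    h = 0.0
    for ctx, row in table.rows().items():
        p_ctx = ctx_counts[ctx] / total
        for p in row.values():
            if p > 0.0:
                h -= p_ctx * p * math.log2(p)
    return max(h, 0.0)


def mutual_information(table: TransitionTable) -> float:
    """MI = H(next) - H(next | context) in bits; requires order >= 1."""
    if table.order < 1:
        raise ValueError("mutual information needs a context variable (order >= 1)")
    marginal = table.next_marginal()
    h_y = -sum(p * math.log2(p) for p in marginal.values() if p > 0.0)
    mi = h_y - conditional_entropy(table)
    return max(mi, 0.0)


def weighted_average_tp(values_and_weights: Sequence[tuple[float, float]]) -> float | None:
    """Occurrence-weighted average: Σ w·tp / Σ w; None when total weight is 0."""
    total_w = sum(w for _, w in values_and_weights)
    if total_w == 0:
        return None
    return sum(tp * w for tp, w in values_and_weights) / total_w


@dataclass
class PieceProfile:
    """Per piece × order: pooled-table entropy/MI plus per-phrase weighted TPs."""

    piece_no: int
    order: int
    conditional_entropy_bits: float
    mutual_information_bits: float | None  # None at order 0
    phrase_tp: dict[tuple[int, ...], float] = field(default_factory=dict)

    def phrase_ic_bits(self) -> dict[tuple[int, ...], float]:
        return {k: information_content(v) for k, v in self.phrase_tp.items() if v > 0}


def piece_phrase_tp(
    movement_tables: Sequence[TransitionTable], pattern: RelativePattern
) -> float | None:
    """Weighted-average TP of one pattern across a piece's movements.

    Each movement contributes its TP weighted by the pattern's occurrence
    count there; movements where the pattern is absent contribute nothing.
    Returns None when the pattern occurs in no movement.
    """
    pairs: list[tuple[float, float]] = []
    for table in movement_tables:
        count = table.pattern_count(pattern)
        if count > 0:
            tp = table.conditional_probability(pattern.context, pattern.next)
            pairs.append((tp, float(count)))
    return weighted_average_tp(pairs)


def piece_profiles(
    movement_streams: Mapping[int, Sequence[PatternStream]],
    order: int,
    phrases: Sequence[RelativePattern] = (),
) -> dict[int, PieceProfile]:
    """Build per-piece profiles at one order.

    ``movement_streams`` maps piece_no to that piece's movement streams (all
    of ``order``).  Entropy and MI come from the piece-level pooled table;
    phrase TPs from occurrence-weighted averaging over movement tables.
    """
    profiles: dict[int, PieceProfile] = {}
    for piece_no, streams in movement_streams.items():
        tables = [estimate_table(s) for s in streams if len(s) > 0]
        if not tables:
            continue
        pooled = pool_tables(tables)
        entropy = conditional_entropy(pooled)
        mi = mutual_information(pooled) if order >= 1 else None
        phrase_tp: dict[tuple[int, ...], float] = {}
        for pattern in phrases:
            tp = piece_phrase_tp(tables, pattern)
            if tp is not None:
                phrase_tp[pattern.offsets] = tp
        profiles[piece_no] = PieceProfile(
            piece_no=piece_no,
            order=order,
            conditional_entropy_bits=entropy,
            mutual_information_bits=mi,
            phrase_tp=phrase_tp,
        )
    return profiles
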