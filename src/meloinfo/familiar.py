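"""Ubiquitous ("familiar") phrase identification across a corpus.

A familiar phrase at order n is a relative-interval pattern that occurs at
least once in *every* piece of the corpus — ubiquity is defined at piece
level, so one occurrence in any movement of a piece counts for that piece.
Per piece, the familiar set is summarized by the unweighted mean (each
phrase counting equally) of each phrase's movement-weighted TP.

The package ships a reference fixture transcribing the phrase inventory
published for the 32 Beethoven piano sonatas, by Markov order.  The source
analysis states 37 first-order phrases in its text while listing 13; the
fixture preserves the listed patterns and carries the stated counts so
validation can surface the discrepancy rather than silently resolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .encoding import RelativePattern, parse_pattern_label, pattern_label
from .markov import TransitionTable, piece_phrase_tp

__all__ = [
    "FamiliarPhraseSet",
    "find_ubiquitous",
    "read_pattern_fixture",
    "load_reference_patterns",
    "REFERENCE_FIXTURE_NAME",
]

REFERENCE_FIXTURE_NAME = "beethoven_sonata_ubiquitous_patterns.tsv"


@dataclass
class FamiliarPhraseSet:
    order: int
    patterns: tuple[RelativePattern, ...]
    per_piece_mean_tp: dict[int, float] = field(default_factory=dict)

    def labels(self) -> list[str]:
        return [pattern_label(p) for p in self.patterns]


def find_ubiquitous(
    piece_movement_tables: Mapping[int, Sequence[TransitionTable]], order: int
) -> FamiliarPhraseSet:
    """Patterns with positive count in every piece, plus per-piece mean TPs.

    ``piece_movement_tables`` maps piece_no to that piece's movement-level
    transition tables (all of ``order``).  Requires at least two pieces.
    """
    if len(piece_movement_tables) < 2:
        raise ValueError("ubiquity needs a corpus of at least 2 pieces")
    for piece_no, tables in piece_movement_tables.items():
        for t in tables:
            if t.order != order:
                raise ValueError(f"piece {piece_no} has a table of order {t.order}, expected {order}")

    piece_patterns: dict[int, set[tuple[tuple[int, ...], int]]] = {}
    for piece_no, tables in piece_movement_tables.items():
        keys: set[tuple[tuple[int, ...], int]] = set()
        for t in tables:
            keys.update(k for k, c in t.counts.items() if c > 0)
        piece_patterns[piece_no] = keys

    common = set.intersection(*piece_patterns.values()) if piece_patterns else set()
    patterns = tuple(
        sorted(
            (RelativePattern(order=order, offsets=ctx + (nxt,)) for ctx, nxt in common),
            key=lambda p: p.offsets,
        )
    )

    per_piece: dict[int, float] = {}
    for piece_no, tables in piece_movement_tables.items():
        tps = []
        for pattern in patterns:
            tp = piece_phrase_tp(tables, pattern)
            if tp is not None:
                tps.append(tp)
        if tps:
            per_piece[piece_no] = sum(tps) / len(tps)
    return FamiliarPhraseSet(order=order, patterns=patterns, per_piece_mean_tp=per_piece)


def read_pattern_fixture(path) -> tuple[dict[int, list[RelativePattern]], dict[int, int]]:
    """Parse a TSV of (order, pattern-label[, stated_count]) rows.

    Returns (patterns per order, stated counts per order).  Stated counts may
    disagree with the number of listed patterns; callers decide whether to
    warn.  Malformed labels raise with row position.
    """
    path = Path(path)
    patterns: dict[int, list[RelativePattern]] = {}
    stated: dict[int, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            cols = text.split("\t")
            if cols[0] == "order":
                continue
            order = int(cols[0])
            try:
                pattern = parse_pattern_label(cols[1], order=order)
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}, column 2: {exc}") from None
            patterns.setdefault(order, []).append(pattern)
            if len(cols) > 2 and cols[2]:
                stated[order] = int(cols[2])
    return patterns, stated


def load_reference_patterns(warn=None) -> dict[int, list[RelativePattern]]:
    """Load the packaged 32-sonata ubiquitous-pattern inventory.

    When a stated per-order phrase count disagrees with the number of listed
    patterns, the discrepancy is passed to ``warn`` (a callable taking a
    message) instead of being resolved.
    """
    with resources.as_file(
        resources.files("meloinfo").joinpath("data", REFERENCE_FIXTURE_NAME)
    ) as path:
        patterns, stated = read_pattern_fixture(path)
    if warn is not None:
        for order, n_stated in stated.items():
            n_listed = len(patterns.get(order, []))
            if n_listed != n_stated:
                warn(
                    f"order {order}: inventory lists {n_listed} patterns but the source "
                    f"analysis states {n_stated}; kept as listed"
                )
    return patterns
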