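"""Relative-interval pattern encoding of melody lines.

An order-``n`` pattern spans a window of ``n + 2`` consecutive notes.  Every
note after the first is expressed as its signed semitone offset from the
window's *first* note (the leading 0 of the first note is implicit and not
stored), so a window yields ``n + 1`` offsets: ``n`` context offsets plus one
"next" offset.  Encoding is therefore invariant under transposition of the
whole line — the statistics describe interval shape, not key.  A descending
five-note scale fragment such as C5 B♭4 A4 G4 F4 encodes at order 3 as
``[-2, -3, -5, -7]``.

Windows slide one note at a time and never cross movement boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .score_io import MelodyLine

__all__ = [
    "RelativePattern",
    "PatternStream",
    "encode",
    "pattern_label",
    "parse_pattern_label",
]

MAX_STANDARD_ORDER = 3


@dataclass(frozen=True)
class RelativePattern:
    """Offsets of an order-n window relative to its first note (n+1 values)."""

    order: int
    offsets: tuple[int, ...]

    def __post_init__(self):
        if len(self.offsets) != self.order + 1:
            raise ValueError(
                f"order {self.order} pattern needs {self.order + 1} offsets, got {len(self.offsets)}"
            )

    @property
    def context(self) -> tuple[int, ...]:
        return self.offsets[:-1]

    @property
    def next(self) -> int:
        return self.offsets[-1]


@dataclass(frozen=True)
class PatternStream:
    """Ordered (context, next) pairs of one order for one movement."""

    piece_no: int
    movement_no: int
    order: int
    pairs: tuple[tuple[tuple[int, ...], int], ...]

    def __len__(self) -> int:
        return len(self.pairs)


def encode(line: MelodyLine, order: int) -> PatternStream:
    """Encode a melody line as an order-``order`` pattern stream.

    A line of length L yields ``max(0, L - order - 1)`` pairs; a line too
    short for a single window yields an empty stream.
    """
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    pitches = line.pitches
    width = order + 2
    pairs = []
    for start in range(len(pitches) - width + 1):
        first = pitches[start]
        offsets = tuple(pitches[start + j] - first for j in range(1, width))
        pairs.append((offsets[:-1], offsets[-1]))
    return PatternStream(
        piece_no=line.piece_no,
        movement_no=line.movement_no,
        order=order,
        pairs=tuple(pairs),
    )


def pattern_label(pattern: RelativePattern | tuple[int, ...]) -> str:
    """Render a pattern as a bracketed offset list, e.g. ``[-2,-4,-5]``."""
    offsets = pattern.offsets if isinstance(pattern, RelativePattern) else tuple(pattern)
    return "[" + ",".join(str(o) for o in offsets) + "]"


def parse_pattern_label(label: str, order: int | None = None) -> RelativePattern:
    """Parse ``[-2,-4,-5]`` (ASCII or U+2212 minus) back into a pattern."""
    text = label.strip().replace("−", "-")
    if not (text.startswith("[") and text.endswith("]")):
        raise ValueError(f"malformed pattern label {label!r}: missing brackets")
    body = text[1:-1].strip()
    if not body:
        raise ValueError(f"malformed pattern label {label!r}: empty offset list")
    try:
        offsets = tuple(int(tok.strip()) for tok in body.split(","))
    except ValueError:
        raise ValueError(f"malformed pattern label {label!r}: non-integer offset") from None
    inferred = len(offsets) - 1
    if order is not None and order != inferred:
        raise ValueError(f"label {label!r} has order {inferred}, expected {order}")
    return RelativePattern(order=inferred, offsets=offsets)
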