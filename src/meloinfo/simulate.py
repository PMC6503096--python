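"""Synthetic melodic corpora with known statistical structure.

The generator produces corpora shaped like the study design the analysis
assumes: pieces grouped into lifetime periods, each piece made of several
movements, each movement a melody sampled from an order-n Markov model over
relative-interval patterns.  Three properties are controlled directly:

* the per-period **transition structure** — every piece draws its own table
  from the period's parameters, so pieces vary within a period (without
  that, a between-period ANOVA would have no honest error term);
* **planted familiar phrases** — designated offset patterns given an exact
  target TP in every piece's table, and additionally spliced once into each
  piece so ubiquity holds even in short corpora;
* **row entropy** — each context row is a symmetric Dirichlet draw whose
  concentration parameter tunes how peaked (low entropy) or flat (high
  entropy) the next-offset distribution is.

Tables are built in the same relative-offset space the encoder produces.
Contexts are the cumulative sums of interval tuples from a fixed interval
alphabet; a context's successors are ``last offset + interval``.  That
context space is closed under the window-rebasing dynamics of relative
encoding, so chain walks never reach a context outside the table, and every
planted offset pattern corresponds to exactly one table entry.

The default "beethoven-like" scenario mirrors the study's corpus layout:
32 pieces split 14 / 13 / 5 into early / middle / late periods, 3 movements
per piece, with the late period given a lowered familiar-phrase TP
(0.6 -> 0.3) and flatter rows (higher conditional entropy).
"""

from __future__ import annotations

import itertools
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import RelativePattern, encode, pattern_label
from .score_io import MelodyLine, write_plaintext_sequence

__all__ = [
    "GeneratorTable",
    "PeriodSpec",
    "ScenarioConfig",
    "GeneratedCorpus",
    "ScenarioConfigError",
    "sample_transition_table",
    "generate_melody",
    "build_scenario",
    "beethoven_like",
    "null_scenario",
    "DEFAULT_ALPHABET",
]

DEFAULT_ALPHABET = (-3, -2, -1, 1, 2, 3)

Context = tuple[int, ...]


class ScenarioConfigError(ValueError):
    """Invalid generator configuration (bad counts, TPs, or planted mass)."""


@dataclass
class GeneratorTable:
    """Ground-truth conditional distributions P(next offset | context offsets)."""

    order: int
    rows: dict[Context, dict[int, float]]

    def conditional_probability(self, context: Context, nxt: int) -> float:
        return self.rows[context].get(nxt, 0.0)

    def row_entropy(self, context: Context) -> float:
        return -sum(p * math.log2(p) for p in self.rows[context].values() if p > 0.0)

    def mean_row_entropy(self, weights: dict[Context, float] | None = None) -> float:
        """Row entropies averaged uniformly or by the given context weights."""
        if weights is None:
            return float(np.mean([self.row_entropy(c) for c in self.rows]))
        total = sum(weights.values())
        return sum(
            (w / total) * self.row_entropy(c) for c, w in weights.items() if c in self.rows
        )


def _contexts(alphabet: tuple[int, ...], order: int) -> list[Context]:
    if order == 0:
        return [()]
    out = []
    for steps in itertools.product(alphabet, repeat=order):
        out.append(tuple(np.cumsum(steps).tolist()))
    return sorted(set(out))


def _successors(context: Context, alphabet: tuple[int, ...], order: int) -> list[int]:
    base = 0 if order == 0 else context[-1]
    return [base + d for d in alphabet]


def sample_transition_table(
    alphabet: tuple[int, ...],
    order: int,
    concentration: float,
    planted: dict[RelativePattern, float] | None = None,
    seed: int | np.random.Generator = 0,
) -> GeneratorTable:
    """Draw a random table: symmetric-Dirichlet rows with planted entries fixed.

    Each context row is Dirichlet(concentration) over the context's
    successors; planted (pattern -> TP) entries are then overwritten to their
    targets and the remaining mass renormalized.  Large concentrations give
    near-uniform rows (entropy near log2 K); small ones give peaked rows.
    """
    if concentration <= 0:
        raise ScenarioConfigError(f"concentration must be > 0, got {concentration}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted = planted or {}

    planted_by_context: dict[Context, dict[int, float]] = {}
    for pattern, tp in planted.items():
        if pattern.order != order:
            raise ScenarioConfigError(
                f"planted pattern {pattern_label(pattern)} has order {pattern.order}, table is order {order}"
            )
        if not 0.0 < tp < 1.0:
            raise ScenarioConfigError(f"planted TP must be in (0,1), got {tp}")
        planted_by_context.setdefault(pattern.context, {})[pattern.next] = tp
    for ctx, entries in planted_by_context.items():
        if sum(entries.values()) >= 1.0:
            raise ScenarioConfigError(
                f"planted mass {sum(entries.values())} >= 1 in context {ctx}"
            )

    rows: dict[Context, dict[int, float]] = {}
    for ctx in _contexts(alphabet, order):
        succ = _successors(ctx, alphabet, order)
        probs = rng.dirichlet(np.full(len(succ), concentration))
        row = dict(zip(succ, probs.tolist()))
        fixed = planted_by_context.get(ctx, {})
        if fixed:
            for nxt in fixed:
                if nxt not in row:
                    raise ScenarioConfigError(
                        f"planted next offset {nxt} unreachable from context {ctx} "
                        f"with alphabet {alphabet}"
                    )
            free_mass = 1.0 - sum(fixed.values())
            free_total = sum(p for nxt, p in row.items() if nxt not in fixed)
            for nxt in row:
                if nxt in fixed:
                    row[nxt] = fixed[nxt]
                else:
                    row[nxt] = row[nxt] / free_total * free_mass if free_total > 0 else free_mass / (len(row) - len(fixed))
        rows[ctx] = row
    return GeneratorTable(order=order, rows=rows)


def _rebase(context: Context, nxt: int) -> Context:
    first = context[0]
    return tuple(o - first for o in context[1:]) + (nxt - first,)


def generate_melody(
    table: GeneratorTable,
    length: int,
    seed: int | np.random.Generator = 0,
    start_pitch: int = 60,
    piece_no: int = 0,
    movement_no: int = 1,
) -> MelodyLine:
    """Walk the chain for ``length`` notes, anchored at ``start_pitch``.

    The walk starts from a uniformly chosen context; re-encoding the output
    recovers a pattern stream whose empirical conditionals converge to the
    table rows.  Absolute pitch is cosmetic (relative encoding removes it).
    """
    order = table.order
    if length < order + 2:
        raise ValueError(f"length must be >= order + 2 = {order + 2}, got {length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    contexts = list(table.rows)

    # Precompute cumulative rows for fast categorical sampling.
    cum: dict[Context, tuple[list[float], list[int]]] = {}
    for ctx, row in table.rows.items():
        nxts = list(row)
        probs = np.cumsum([row[n] for n in nxts])
        probs[-1] = 1.0
        cum[ctx] = (probs.tolist(), nxts)

    pitches: list[int] = [start_pitch]
    if order == 0:
        ctx: Context = ()
    else:
        ctx = contexts[int(rng.integers(len(contexts)))]
        pitches.extend(start_pitch + o for o in ctx)
    while len(pitches) < length:
        if ctx not in table.rows:  # unreachable by construction; restart defensively
            ctx = contexts[int(rng.integers(len(contexts)))]
            continue
        cps, nxts = cum[ctx]
        y = nxts[bisect_left(cps, rng.random())]
        interval = y if order == 0 else y - ctx[-1]
        pitches.append(pitches[-1] + interval)
        if order > 0:
            ctx = _rebase(ctx, y)
    return MelodyLine(piece_no=piece_no, movement_no=movement_no, pitches=tuple(pitches[:length]))


def _splice_patterns(
    line: MelodyLine, patterns: Sequence[RelativePattern], rng: np.random.Generator
) -> MelodyLine:
    """Insert one full window per pattern at random, non-interfering positions.

    Insertion points are indices into the *original* melody, so a run can
    never land inside another inserted run (adjacent runs stay intact).
    """
    pitches = list(line.pitches)
    positions = sorted(
        (int(rng.integers(1, max(2, len(pitches)))) for _ in patterns), reverse=True
    )
    for pattern, pos in zip(patterns, positions):
        anchor = pitches[pos - 1]
        run = [anchor] + [anchor + o for o in pattern.offsets]
        pitches[pos:pos] = run
    return MelodyLine(line.piece_no, line.movement_no, tuple(pitches))


@dataclass(frozen=True)
class PeriodSpec:
    label: str
    piece_count: int
    movements_per_piece: int
    notes_per_movement: int
    concentration: float
    familiar_tp: dict[RelativePattern, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int
    order: int
    periods: tuple[PeriodSpec, ...]
    alphabet: tuple[int, ...] = DEFAULT_ALPHABET

    def validate(self) -> None:
        if not self.periods:
            raise ScenarioConfigError("scenario needs at least one period")
        for spec in self.periods:
            if spec.piece_count < 2:
                raise ScenarioConfigError(
                    f"period {spec.label!r} has {spec.piece_count} pieces; >= 2 required"
                )
            if spec.movements_per_piece < 1 or spec.notes_per_movement < self.order + 2:
                raise ScenarioConfigError(f"period {spec.label!r}: invalid movement layout")
            if spec.concentration <= 0:
                raise ScenarioConfigError(f"period {spec.label!r}: concentration must be > 0")
            for pattern, tp in spec.familiar_tp.items():
                if not 0.0 < tp < 1.0:
                    raise ScenarioConfigError(
                        f"period {spec.label!r}: TP for {pattern_label(pattern)} must be in (0,1)"
                    )


@dataclass
class GeneratedCorpus:
    config: ScenarioConfig
    periods: dict[int, str]  # piece_no -> period label
    movements: dict[tuple[int, int], MelodyLine]
    truth_tables: dict[int, GeneratorTable]  # piece_no -> generator table
    manifest_path: Path | None = None


def build_scenario(config: ScenarioConfig, out_dir: str | Path | None = None) -> GeneratedCorpus:
    """Generate a full corpus; optionally write it to disk.

    Writing produces the plain-text sequence files, a manifest TSV, and the
    ground-truth tables as TSV.  Every planted pattern is verified present in
    every piece after generation (splicing guarantees this).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    periods: dict[int, str] = {}
    movements: dict[tuple[int, int], MelodyLine] = {}
    truth: dict[int, GeneratorTable] = {}

    piece_no = 0
    for spec in config.periods:
        for _ in range(spec.piece_count):
            piece_no += 1
            periods[piece_no] = spec.label
            table = sample_transition_table(
                config.alphabet, config.order, spec.concentration,
                planted=spec.familiar_tp, seed=rng,
            )
            truth[piece_no] = table
            for mvt in range(1, spec.movements_per_piece + 1):
                line = generate_melody(
                    table, spec.notes_per_movement, seed=rng,
                    piece_no=piece_no, movement_no=mvt,
                )
                if mvt == 1 and spec.familiar_tp:
                    line = _splice_patterns(line, list(spec.familiar_tp), rng)
                movements[(piece_no, mvt)] = line

    # Verify planted ubiquity.
    for spec in config.periods:
        for pn, label in periods.items():
            if label != spec.label:
                continue
            for pattern in spec.familiar_tp:
                found = any(
                    (pattern.context, pattern.next)
                    in set(encode(movements[(pn, m)], config.order).pairs)
                    for m in range(1, spec.movements_per_piece + 1)
                )
                if not found:
                    raise RuntimeError(
                        f"planted pattern {pattern_label(pattern)} absent from piece {pn}"
                    )

    corpus = GeneratedCorpus(config=config, periods=periods, movements=movements, truth_tables=truth)
    if out_dir is not None:
        corpus.manifest_path = _write_corpus(corpus, Path(out_dir))
    return corpus


def _write_corpus(corpus: GeneratedCorpus, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_dir = out_dir / "sequences"
    seq_dir.mkdir(exist_ok=True)
    manifest_path = out_dir / "manifest.tsv"
    with manifest_path.open("w") as fh:
        fh.write("piece_no\topus\tmovement_no\tperiod\tpath\n")
        for (pn, mvt), line in sorted(corpus.movements.items()):
            rel = f"sequences/piece{pn:02d}_mvt{mvt}.txt"
            write_plaintext_sequence(out_dir / rel, line)
            fh.write(f"{pn}\tsynthetic-{pn}\t{mvt}\t{corpus.periods[pn]}\t{rel}\n")
    with (out_dir / "truth_tables.tsv").open("w") as fh:
        fh.write("piece_no\tcontext\tnext\tprobability\n")
        for pn, table in sorted(corpus.truth_tables.items()):
            for ctx, row in sorted(table.rows.items()):
                ctx_label = ";".join(str(o) for o in ctx)
                for nxt, p in sorted(row.items()):
                    fh.write(f"{pn}\t{ctx_label}\t{nxt}\t{p:.12g}\n")
    return manifest_path


# ---------------------------------------------------------------------------
# Canned scenarios
# ---------------------------------------------------------------------------

_PLANTED_ORDER2 = (
    RelativePattern(2, (-2, -4, -5)),
    RelativePattern(2, (-2, -3, -5)),
    RelativePattern(2, (-1, -3, -5)),
)


def beethoven_like(seed: int, notes_per_movement: int = 2000, order: int = 2) -> ScenarioConfig:
    """Corpus shaped like the 32-sonata study with a late-period shift.

    Early/middle/late have 14/13/5 pieces and 3 movements each; planted
    familiar phrases carry TP 0.6 in early and middle but 0.3 in late, and
    late-period rows are drawn flatter (concentration 5.0 vs 0.5), raising
    conditional entropy.
    """
    planted = _planted_for_order(order)
    return ScenarioConfig(
        seed=seed,
        order=order,
        periods=(
            PeriodSpec("early", 14, 3, notes_per_movement, 0.5, {p: 0.6 for p in planted}),
            PeriodSpec("middle", 13, 3, notes_per_movement, 0.5, {p: 0.6 for p in planted}),
            PeriodSpec("late", 5, 3, notes_per_movement, 5.0, {p: 0.3 for p in planted}),
        ),
    )


def null_scenario(seed: int, notes_per_movement: int = 2000, order: int = 2) -> ScenarioConfig:
    """Identical parameters in every period: no true period effect."""
    planted = _planted_for_order(order)
    return ScenarioConfig(
        seed=seed,
        order=order,
        periods=(
            PeriodSpec("early", 14, 3, notes_per_movement, 0.5, {p: 0.6 for p in planted}),
            PeriodSpec("middle", 13, 3, notes_per_movement, 0.5, {p: 0.6 for p in planted}),
            PeriodSpec("late", 5, 3, notes_per_movement, 0.5, {p: 0.6 for p in planted}),
        ),
    )


def _planted_for_order(order: int) -> tuple[RelativePattern, ...]:
    if order == 2:
        return _PLANTED_ORDER2
    if order == 3:
        return (
            RelativePattern(3, (-2, -3, -5, -7)),
            RelativePattern(3, (-2, -4, -5, -7)),
            RelativePattern(3, (-1, -3, -5, -6)),
        )
    if order == 1:
        # self-sustaining under rebasing: context (1) -> (1), (-1) -> (-1)
        return (RelativePattern(1, (1, 2)), RelativePattern(1, (-1, -2)))
    return (RelativePattern(0, (-2,)),)
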