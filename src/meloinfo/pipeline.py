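"""End-to-end orchestration: melodies -> streams -> profiles -> lifetime statistics.

``analyze_corpus`` is the in-memory workhorse; ``run_all`` wraps it with
manifest loading, TSV/JSON output, and per-stage logging.  All intermediate
artifacts are plain TSV/JSON so any stage can be audited by hand, and a
rerun on the same inputs is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import familiar as fam
from . import lifetime, markov
from .encoding import PatternStream, encode, pattern_label
from .score_io import MelodyLine, load_corpus

__all__ = ["RunConfig", "AnalysisResult", "analyze_corpus", "run_all", "StageError"]

DEFAULT_ORDERS = (0, 1, 2, 3)

MEASURES = ("familiar_tp", "entropy", "mi")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending unit."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    manifest_path: Path
    out_dir: Path
    orders: tuple[int, ...] = DEFAULT_ORDERS
    period_map: dict[int, str] | None = None  # None -> infer from manifest labels
    seed: int = 0
    run_anova: bool = True
    log: Callable[[str], None] | None = None

    def __post_init__(self):
        self.manifest_path = Path(self.manifest_path)
        self.out_dir = Path(self.out_dir)
        bad = [o for o in self.orders if o < 0]
        if bad:
            raise ValueError(f"negative orders: {bad}")


@dataclass
class AnalysisResult:
    orders: tuple[int, ...]
    periods: dict[int, str]
    familiar_sets: dict[int, fam.FamiliarPhraseSet]
    profiles: dict[int, dict[int, markov.PieceProfile]]  # order -> piece -> profile
    long_table: pd.DataFrame  # piece_no, period, order, measure, value
    anovas: dict[str, list[lifetime.AnovaResult]] = field(default_factory=dict)
    posthocs: dict[str, list[lifetime.PosthocResult]] = field(default_factory=dict)
    correlations: list[lifetime.CorrelationResult] = field(default_factory=list)

    def measure_table(self, measure: str) -> pd.DataFrame:
        sub = self.long_table[self.long_table["measure"] == measure]
        return sub.drop(columns=["measure"]).reset_index(drop=True)

    def summary(self) -> dict:
        """Period x order means and sds per measure (numeric panel view)."""
        out: dict = {}
        for measure in sorted(self.long_table["measure"].unique()):
            sub = self.long_table[self.long_table["measure"] == measure]
            grp = sub.groupby(["period", "order"])["value"].agg(["mean", "std", "count"])
            out[measure] = {
                f"{period}/order{order}": {
                    "mean": float(row["mean"]),
                    "sd": float(row["std"]),
                    "n": int(row["count"]),
                }
                for (period, order), row in grp.iterrows()
            }
        return out


def _movement_streams_by_piece(
    movements: Mapping[tuple[int, int], MelodyLine], order: int
) -> dict[int, list[PatternStream]]:
    by_piece: dict[int, list[PatternStream]] = {}
    for (piece_no, _), line in sorted(movements.items()):
        by_piece.setdefault(piece_no, []).append(encode(line, order))
    return by_piece


def analyze_corpus(
    movements: Mapping[tuple[int, int], MelodyLine],
    periods: Mapping[int, str],
    orders: Sequence[int] = DEFAULT_ORDERS,
    run_anova: bool = True,
    log: Callable[[str], None] | None = None,
) -> AnalysisResult:
    """Run the full analysis on in-memory movements.

    Per order: encode movements, mine the corpus-wide familiar-phrase set,
    build per-piece profiles (pooled-count entropy and MI, movement-weighted
    familiar TPs), then assemble the long table and — when ``run_anova`` —
    the mixed ANOVAs, Bonferroni post-hocs, and TP-entropy correlations.
    """
    orders = tuple(orders)
    pieces = sorted({pn for pn, _ in movements})
    unmapped = [p for p in pieces if p not in periods]
    if unmapped:
        raise StageError("periods", f"pieces without period label: {unmapped}")

    familiar_sets: dict[int, fam.FamiliarPhraseSet] = {}
    profiles: dict[int, dict[int, markov.PieceProfile]] = {}
    rows: list[dict] = []

    for order in orders:
        streams = _movement_streams_by_piece(movements, order)
        tables = {
            pn: [markov.estimate_table(s) for s in ss if len(s) > 0]
            for pn, ss in streams.items()
        }
        empty = [pn for pn, ts in tables.items() if not ts]
        if empty:
            raise StageError("encode", f"order {order}: no windows for pieces {empty}")
        phrase_set = fam.find_ubiquitous(tables, order)
        if not phrase_set.patterns:
            raise StageError(
                "familiar", f"order {order}: no pattern occurs in every piece"
            )
        familiar_sets[order] = phrase_set
        if log:
            log(f"order {order}: {len(phrase_set.patterns)} familiar patterns")
        prof = markov.piece_profiles(streams, order, phrases=phrase_set.patterns)
        profiles[order] = prof
        for pn in pieces:
            p = prof[pn]
            rows.append(
                dict(piece_no=pn, period=periods[pn], order=order,
                     measure="familiar_tp", value=phrase_set.per_piece_mean_tp[pn])
            )
            rows.append(
                dict(piece_no=pn, period=periods[pn], order=order,
                     measure="entropy", value=p.conditional_entropy_bits)
            )
            if order >= 1:
                rows.append(
                    dict(piece_no=pn, period=periods[pn], order=order,
                         measure="mi", value=p.mutual_information_bits)
                )

    long_table = pd.DataFrame(rows)
    result = AnalysisResult(
        orders=orders, periods=dict(periods),
        familiar_sets=familiar_sets, profiles=profiles, long_table=long_table,
    )

    if run_anova and len(set(periods.values())) >= 2:
        for measure in MEASURES:
            table = result.measure_table(measure)
            if table.empty or table["order"].nunique() < 2:
                continue
            try:
                result.anovas[measure] = lifetime.mixed_anova(table)
                result.posthocs[measure] = lifetime.bonferroni_posthoc(table, "period")
                result.posthocs[f"{measure} x order"] = lifetime.bonferroni_posthoc(
                    table, "period x order"
                )
            except lifetime.DesignError as exc:
                raise StageError("anova", f"measure {measure}: {exc}") from exc
        for order in orders:
            phrase_set = familiar_sets[order]
            ent = {pn: profiles[order][pn].conditional_entropy_bits for pn in pieces}
            try:
                result.correlations.append(
                    lifetime.tp_entropy_correlation(phrase_set.per_piece_mean_tp, ent, order)
                )
            except ValueError:
                pass  # degenerate order (e.g. zero variance); omitted from output
    return result


# ---------------------------------------------------------------------------
# Disk-facing run
# ---------------------------------------------------------------------------


def run_all(config: RunConfig) -> AnalysisResult:
    """Load a corpus from its manifest, analyze it, and write all outputs."""
    log = config.log or (lambda msg: None)
    try:
        manifest, movements = load_corpus(config.manifest_path, log=log)
    except Exception as exc:
        raise StageError("load", str(exc)) from exc
    if config.period_map is not None:
        periods = lifetime.assign_periods(
            sorted({pn for pn, _ in movements}), config.period_map
        )
    else:
        periods = {e.piece_no: e.period_label for e in manifest.entries}

    result = analyze_corpus(
        movements, periods, orders=config.orders, run_anova=config.run_anova, log=log
    )
    write_outputs(result, config.out_dir)
    return result


def write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    result.long_table.sort_values(["measure", "order", "piece_no"]).to_csv(
        out_dir / "long_table.tsv", sep="\t", index=False, float_format="%.10g"
    )

    with (out_dir / "familiar_phrases.tsv").open("w") as fh:
        fh.write("order\tpattern\tpiece_no\ttp\n")
        for order, phrase_set in sorted(result.familiar_sets.items()):
            for pattern in phrase_set.patterns:
                for pn in sorted(result.profiles[order]):
                    tp = result.profiles[order][pn].phrase_tp.get(pattern.offsets)
                    if tp is not None:
                        fh.write(f"{order}\t{pattern_label(pattern)}\t{pn}\t{tp:.10g}\n")

    with (out_dir / "profiles.tsv").open("w") as fh:
        fh.write("piece_no\torder\tentropy_bits\tmi_bits\tmean_familiar_tp\tmean_familiar_ic_bits\n")
        for order, prof in sorted(result.profiles.items()):
            for pn, p in sorted(prof.items()):
                tp = result.familiar_sets[order].per_piece_mean_tp.get(pn)
                mi = "" if p.mutual_information_bits is None else f"{p.mutual_information_bits:.10g}"
                ic = "" if not tp else f"{markov.information_content(tp):.10g}"
                tp_s = "" if tp is None else f"{tp:.10g}"
                fh.write(f"{pn}\t{order}\t{p.conditional_entropy_bits:.10g}\t{mi}\t{tp_s}\t{ic}\n")

    if result.anovas:
        with (out_dir / "anova.tsv").open("w") as fh:
            fh.write("measure\teffect\tdf1\tdf2\tF\tp\tpartial_eta2\tgg_corrected\n")
            for measure, effects in sorted(result.anovas.items()):
                for e in effects:
                    fh.write(
                        f"{measure}\t{e.effect}\t{e.df_num:.6g}\t{e.df_den:.6g}\t"
                        f"{e.F:.10g}\t{e.p:.10g}\t{e.partial_eta_sq:.10g}\t{int(e.sphericity_corrected)}\n"
                    )
        with (out_dir / "posthoc.tsv").open("w") as fh:
            fh.write("measure\tfamily\tlevel_a\tlevel_b\tmean_diff\tp_raw\tp_bonferroni\tdirection\n")
            for measure, comps in sorted(result.posthocs.items()):
                for c in comps:
                    fh.write(
                        f"{measure}\t{c.family}\t{c.level_a}\t{c.level_b}\t"
                        f"{c.mean_diff:.10g}\t{c.p_raw:.10g}\t{c.p_adjusted:.10g}\t{c.direction}\n"
                    )
    if result.correlations:
        with (out_dir / "correlation.tsv").open("w") as fh:
            fh.write("order\tr\tp\tn\n")
            for c in result.correlations:
                fh.write(f"{c.order}\t{c.r:.10g}\t{c.p:.10g}\t{c.n}\n")

    summary = {
        "panels": result.summary(),
        "anova": {
            measure: [
                dict(effect=e.effect, df1=e.df_num, df2=e.df_den, F=e.F, p=e.p,
                     partial_eta2=e.partial_eta_sq, gg_corrected=e.sphericity_corrected)
                for e in effects
            ]
            for measure, effects in result.anovas.items()
        },
        "correlations": [
            dict(order=c.order, r=c.r, p=c.p, n=c.n) for c in result.correlations
        ],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
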