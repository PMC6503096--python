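"""Lifetime-period statistics: mixed ANOVA, Bonferroni post-hocs, correlation.

Pieces (sonatas) are the experimental units.  The design is a mixed ANOVA
with Markov order as the within-subject factor and composition period
(early / middle / late) as the between-subjects factor, run separately on
familiar-phrase TP, conditional entropy, and mutual information (MI uses
orders 1-3 only, since order 0 has no context).  Sphericity of the within
effect is checked with Mauchly's test; when rejected at p < 0.05 the
Greenhouse-Geisser correction scales the within dfs (producing fractional
dfs) and the corrected p is reported.  Effect sizes are partial eta squared,
SS_effect / (SS_effect + SS_error).

Post-hoc comparisons are pairwise two-sample t-tests on piece-level means
(for the between factor, averaging over orders; for interactions, within
each order level), Bonferroni-adjusted by multiplying each raw p by the
number of comparisons in its family, capped at 1.

The default piece -> period mapping is the conventional split of
Beethoven's 32 sonatas: early = 1-12, 19, 20; middle = 13-18, 21-27;
late = 28-32.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "DEFAULT_PERIOD_MAP",
    "PERIOD_ORDER",
    "assign_periods",
    "AnovaResult",
    "PosthocResult",
    "CorrelationResult",
    "mixed_anova",
    "bonferroni_posthoc",
    "tp_entropy_correlation",
    "DesignError",
]

PERIOD_ORDER = ("early", "middle", "late")

DEFAULT_PERIOD_MAP: dict[int, str] = {
    **{n: "early" for n in list(range(1, 13)) + [19, 20]},
    **{n: "middle" for n in list(range(13, 19)) + list(range(21, 28))},
    **{n: "late" for n in range(28, 33)},
}


class DesignError(ValueError):
    """The data do not form the complete balanced-within design required."""


def assign_periods(piece_nos, mapping: dict[int, str] | None = None) -> dict[int, str]:
    """Attach a period label to every piece; unmapped pieces are an error."""
    mapping = DEFAULT_PERIOD_MAP if mapping is None else mapping
    missing = [p for p in piece_nos if p not in mapping]
    if missing:
        raise ValueError(f"pieces without a period mapping: {sorted(missing)}")
    return {p: mapping[p] for p in piece_nos}


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    df_num: float
    df_den: float
    F: float
    p: float
    partial_eta_sq: float
    sphericity_corrected: bool = False
    gg_epsilon: float | None = None


@dataclass(frozen=True)
class PosthocResult:
    family: str
    level_a: str
    level_b: str
    mean_diff: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int

    @property
    def direction(self) -> str:
        if self.mean_diff > 0:
            return f"{self.level_a} > {self.level_b}"
        if self.mean_diff < 0:
            return f"{self.level_a} < {self.level_b}"
        return f"{self.level_a} = {self.level_b}"


@dataclass(frozen=True)
class CorrelationResult:
    order: int
    r: float
    p: float
    n: int


def _check_design(table: pd.DataFrame) -> None:
    required = {"piece_no", "period", "order", "value"}
    missing_cols = required - set(table.columns)
    if missing_cols:
        raise DesignError(f"long table missing columns: {sorted(missing_cols)}")
    cells = table.groupby(["piece_no", "order"]).size()
    if (cells != 1).any():
        bad = cells[cells != 1].index.tolist()
        raise DesignError(f"design not complete/balanced at cells {bad[:10]}")
    orders = sorted(table["order"].unique())
    pieces = table["piece_no"].unique()
    expected = len(pieces) * len(orders)
    if len(table) != expected:
        raise DesignError(f"expected {expected} rows for a complete design, got {len(table)}")
    per_period = table.groupby("period")["piece_no"].nunique()
    if (per_period < 2).any():
        raise DesignError(f"need >= 2 pieces per period, got {per_period.to_dict()}")


def mixed_anova(table: pd.DataFrame) -> list[AnovaResult]:
    """Mixed ANOVA on a long table with columns piece_no, period, order, value.

    Returns between (period), within (order), and interaction effects.  The
    within effect's dfs and p are Greenhouse-Geisser corrected when Mauchly's
    test rejects sphericity at p < 0.05 (only possible with >= 3 within
    levels).
    """
    _check_design(table)
    if table["period"].nunique() < 2:
        raise DesignError("between effect undefined with a single period")
    df = table.rename(columns={"piece_no": "subject"}).copy()
    aov = pg.mixed_anova(
        data=df, dv="value", within="order", between="period",
        subject="subject", correction=True, effsize="np2",
    )
    results: list[AnovaResult] = []
    for _, row in aov.iterrows():
        source = str(row["Source"])
        if source == "period":
            effect = "period"
        elif source == "order":
            effect = "order"
        else:
            effect = "period x order"
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        p = float(row["p_unc"])
        corrected = False
        eps = None
        if effect == "order":
            eps_val = row.get("eps")
            p_spher = row.get("p_spher")
            p_gg = row.get("p_GG_corr")
            if (
                eps_val is not None and np.isfinite(eps_val)
                and p_spher is not None and np.isfinite(p_spher)
                and p_spher < 0.05 and p_gg is not None and np.isfinite(p_gg)
            ):
                corrected = True
                eps = float(eps_val)
                df1, df2 = df1 * eps, df2 * eps
                p = float(p_gg)
            elif eps_val is not None and np.isfinite(eps_val):
                eps = float(eps_val)
        results.append(
            AnovaResult(
                effect=effect,
                df_num=df1,
                df_den=df2,
                F=float(row["F"]),
                p=p,
                partial_eta_sq=float(row["np2"]),
                sphericity_corrected=corrected,
                gg_epsilon=eps,
            )
        )
    return results


def _pairwise_t(groups: dict[str, np.ndarray], family: str) -> list[PosthocResult]:
    levels = [lv for lv in PERIOD_ORDER if lv in groups] or sorted(groups)
    pairs = list(itertools.combinations(levels, 2))
    out = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if np.allclose(xa.var(ddof=0) + xb.var(ddof=0), 0.0) and np.isclose(xa.mean(), xb.mean()):
            t, p_raw = 0.0, 1.0
        else:
            t, p_raw = stats.ttest_ind(xa, xb)
            p_raw = float(p_raw)
        out.append(
            PosthocResult(
                family=family,
                level_a=a,
                level_b=b,
                mean_diff=float(xa.mean() - xb.mean()),
                p_raw=p_raw,
                p_adjusted=min(1.0, p_raw * len(pairs)),
                n_comparisons=len(pairs),
            )
        )
    return out


def bonferroni_posthoc(table: pd.DataFrame, effect: str = "period") -> list[PosthocResult]:
    """Pairwise Bonferroni-corrected comparisons for a significant effect.

    ``effect="period"`` compares periods on piece-level means over orders;
    ``effect="period x order"`` runs simple-effects comparisons of periods
    within each order, correcting over all pairs tested.
    """
    _check_design(table)
    if table["period"].nunique() < 2:
        raise ValueError("post-hoc comparison needs >= 2 period levels")
    if effect == "period":
        means = table.groupby(["piece_no", "period"])["value"].mean().reset_index()
        groups = {
            lv: means.loc[means["period"] == lv, "value"].to_numpy()
            for lv in means["period"].unique()
        }
        return _pairwise_t(groups, family="period")
    if effect in ("period x order", "interaction"):
        results: list[PosthocResult] = []
        sub_families: list[tuple[str, dict[str, np.ndarray]]] = []
        for order in sorted(table["order"].unique()):
            sub = table[table["order"] == order]
            groups = {
                lv: sub.loc[sub["period"] == lv, "value"].to_numpy()
                for lv in sub["period"].unique()
            }
            sub_families.append((f"period @ order {order}", groups))
        # Bonferroni over every pair tested across all order levels
        n_total = sum(
            len(list(itertools.combinations(g, 2))) for _, g in sub_families
        )
        for family, groups in sub_families:
            for r in _pairwise_t(groups, family=family):
                results.append(
                    PosthocResult(
                        family=r.family,
                        level_a=r.level_a,
                        level_b=r.level_b,
                        mean_diff=r.mean_diff,
                        p_raw=r.p_raw,
                        p_adjusted=min(1.0, r.p_raw * n_total),
                        n_comparisons=n_total,
                    )
                )
        return results
    raise ValueError(f"unknown effect {effect!r}")


def tp_entropy_correlation(
    tp_by_piece: dict[int, float], entropy_by_piece: dict[int, float], order: int
) -> CorrelationResult:
    """Pearson correlation across pieces between familiar TP and entropy."""
    common = sorted(set(tp_by_piece) & set(entropy_by_piece))
    if len(common) < 3:
        raise ValueError(f"correlation needs >= 3 pieces with both values, got {len(common)}")
    x = np.array([tp_by_piece[p] for p in common], float)
    y = np.array([entropy_by_piece[p] for p in common], float)
    if np.isclose(x.std(), 0.0) or np.isclose(y.std(), 0.0):
        raise ValueError("correlation undefined: zero variance in one variable")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(order=order, r=float(r), p=float(p), n=len(common))
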